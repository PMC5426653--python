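"""Bundled element van-der-Waals radius table (Bondi 1964 values, Å).

Elements missing from the table fall back to :data:`FALLBACK_RADIUS` with a
logged warning; the table name is recorded in run manifests so outputs are
traceable to the radii that produced them.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

TABLE_NAME = "Bondi (1964)"

BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "HE": 1.40,
    "NE": 1.54,
    "AR": 1.88,
    "SI": 2.10,
}

FALLBACK_RADIUS = 1.50

_warned: set[str] = set()


def vdw_radius(element: str) -> float:
    """Radius in Å for an element symbol; unknown symbols use the fallback
    (warned once per element symbol)."""
    key = element.strip().upper()
    r = BONDI_RADII.get(key)
    if r is None:
        if key not in _warned:
            _warned.add(key)
            logger.warning(
                "element %r not in %s table; using fallback radius %.2f Å",
                element, TABLE_NAME, FALLBACK_RADIUS,
            )
        return FALLBACK_RADIUS
    return r
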