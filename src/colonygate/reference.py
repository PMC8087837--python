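"""Reference range-gate tables for the seven taxa.

These are published min/max gate ranges obtained with the FlowCAM /
VisualSpreadsheet workflow on a Danish mesocosm *Microcystis* bloom: for
each class, gates were fitted on 25 and on 50 randomly selected training
images ("25" / "50" columns) and then narrowed to their overlap (the
"Intersection" filter).  The intergeneric panel separates *Cryptomonas*,
*Micractinium* and *Microcystis* (represented by *M. novacekii*); the
intrageneric panel separates the five colonial *Microcystis* morphospecies.

The package uses these tables in two roles:

* as worked examples for the intersection-narrowing step (every row must
  satisfy ``intersection == [max(min25, min50), min(max25, max50)]``), and
* as target envelopes that the synthetic generator's feature distributions
  must fall inside (see :func:`class_envelopes`).

Sizes are in micrometres, signal features in 8-bit grey levels.
"""

from __future__ import annotations

from .particles import (
    AVERAGE_BLUE,
    DIAMETER_ABD,
    EDGE_GRADIENT,
    INTENSITY,
    LENGTH,
    PERIMETER,
    RATIO_RED_BLUE,
    RATIO_RED_GREEN,
    ROUGHNESS,
    SIGMA_INTENSITY,
)

CRYPTOMONAS = "Cryptomonas"
MICRACTINIUM = "Micractinium"
M_AERUGINOSA = "Microcystis aeruginosa"
M_ICHTHYOBLABE = "Microcystis ichthyoblabe"
M_NOVACEKII = "Microcystis novacekii"
M_SMITHII = "Microcystis smithii"
M_WESENBERGII = "Microcystis wesenbergii"

#: The three genus-level classes (*Microcystis* represented by M. novacekii).
INTERGENERIC_CLASSES = (CRYPTOMONAS, MICRACTINIUM, M_NOVACEKII)

#: The five colonial *Microcystis* morphospecies.
INTRAGENERIC_CLASSES = (
    M_AERUGINOSA,
    M_ICHTHYOBLABE,
    M_NOVACEKII,
    M_SMITHII,
    M_WESENBERGII,
)

ALL_CLASSES = (
    CRYPTOMONAS,
    MICRACTINIUM,
    M_AERUGINOSA,
    M_ICHTHYOBLABE,
    M_NOVACEKII,
    M_SMITHII,
    M_WESENBERGII,
)

# {class: {feature: {"25": (lo, hi), "50": (lo, hi), "intersection": (lo, hi)}}}
INTERGENERIC_GATES = {
    CRYPTOMONAS: {
        DIAMETER_ABD: {
            "25": (8.23, 11.53),
            "50": (8.22, 12.72),
            "intersection": (8.23, 11.53),
        },
    },
    MICRACTINIUM: {
        DIAMETER_ABD: {
            "25": (16.19, 40.52),
            "50": (15.85, 40.52),
            "intersection": (16.19, 40.52),
        },
        INTENSITY: {
            "25": (79.20, 105.85),
            "50": (73.64, 105.85),
            "intersection": (79.20, 105.85),
        },
    },
    M_NOVACEKII: {
        DIAMETER_ABD: {
            "25": (45.35, 85.69),
            "50": (33.48, 83.89),
            "intersection": (45.35, 83.89),
        },
        INTENSITY: {
            "25": (49.12, 92.47),
            "50": (40.55, 97.59),
            "intersection": (49.12, 92.47),
        },
    },
}

INTRAGENERIC_GATES = {
    M_AERUGINOSA: {
        AVERAGE_BLUE: {
            "25": (76.28, 101.01),
            "50": (76.08, 97.85),
            "intersection": (76.28, 97.85),
        },
        EDGE_GRADIENT: {
            "25": (99.93, 159.87),
            "50": (96.11, 159.87),
            "intersection": (99.93, 159.87),
        },
        PERIMETER: {
            "25": (391.00, 1620.14),
            "50": (391.00, 1460.73),
            "intersection": (391.00, 1460.73),
        },
        RATIO_RED_BLUE: {
            "25": (1.15, 1.28),
            "50": (1.15, 1.30),
            "intersection": (1.15, 1.28),
        },
        SIGMA_INTENSITY: {
            "25": (23.72, 34.09),
            "50": (23.68, 35.70),
            "intersection": (23.72, 34.09),
        },
    },
    M_ICHTHYOBLABE: {
        AVERAGE_BLUE: {
            "25": (72.02, 96.30),
            "50": (77.64, 96.30),
            "intersection": (77.64, 96.30),
        },
        INTENSITY: {
            "25": (78.76, 110.43),
            "50": (83.81, 110.43),
            "intersection": (83.81, 110.43),
        },
        LENGTH: {
            "25": (56.85, 138.37),
            "50": (60.17, 128.39),
            "intersection": (60.17, 128.39),
        },
        RATIO_RED_BLUE: {
            "25": (1.17, 1.32),
            "50": (1.15, 1.32),
            "intersection": (1.17, 1.32),
        },
        ROUGHNESS: {
            "25": (1.42, 4.16),
            "50": (1.38, 4.16),
            "intersection": (1.42, 4.16),
        },
        SIGMA_INTENSITY: {
            "25": (22.14, 28.37),
            "50": (21.58, 30.97),
            "intersection": (22.14, 28.37),
        },
    },
    M_NOVACEKII: {
        INTENSITY: {
            "25": (48.36, 80.51),
            "50": (46.45, 74.81),
            "intersection": (48.36, 74.81),
        },
    },
    M_SMITHII: {
        INTENSITY: {
            "25": (94.55, 117.32),
            "50": (93.98, 120.00),
            "intersection": (94.55, 117.32),
        },
        RATIO_RED_GREEN: {
            "25": (1.17, 1.35),
            "50": (1.16, 1.39),
            "intersection": (1.17, 1.35),
        },
        ROUGHNESS: {
            "25": (2.19, 10.70),
            "50": (1.58, 10.70),
            "intersection": (2.19, 10.70),
        },
    },
    M_WESENBERGII: {
        AVERAGE_BLUE: {
            "25": (65.24, 85.13),
            "50": (61.31, 85.13),
            "intersection": (65.24, 85.13),
        },
        INTENSITY: {
            "25": (73.59, 98.04),
            "50": (67.25, 98.04),
            "intersection": (73.59, 98.04),
        },
        RATIO_RED_BLUE: {
            "25": (1.19, 1.36),
            "50": (1.19, 1.39),
            "intersection": (1.19, 1.36),
        },
        RATIO_RED_GREEN: {
            "25": (1.17, 1.23),
            "50": (1.15, 1.27),
            "intersection": (1.17, 1.23),
        },
        SIGMA_INTENSITY: {
            "25": (26.89, 43.70),
            "50": (26.10, 47.12),
            "intersection": (26.89, 43.70),
        },
    },
}


def iter_gate_rows():
    """Yield ``(panel, class_name, feature, min25, max25, min50, max50,
    min_int, max_int)`` for every row of both reference panels."""
    for panel, table in (
        ("intergeneric", INTERGENERIC_GATES),
        ("intrageneric", INTRAGENERIC_GATES),
    ):
        for class_name, feats in table.items():
            for feature, cols in feats.items():
                yield (
                    panel,
                    class_name,
                    feature,
                    *cols["25"],
                    *cols["50"],
                    *cols["intersection"],
                )


def class_envelopes(class_name: str) -> dict[str, tuple[float, float]]:
    """Strictest published range per gated feature for ``class_name``.

    Where a (class, feature) pair carries several published ranges (the
    25 / 50 / Intersection columns, and for *M. novacekii* both panels),
    the generator targets their common intersection, so that containment
    inside *every* published range holds simultaneously.
    """
    out: dict[str, tuple[float, float]] = {}
    for table in (INTERGENERIC_GATES, INTRAGENERIC_GATES):
        for feature, cols in table.get(class_name, {}).items():
            lo = max(c[0] for c in cols.values())
            hi = min(c[1] for c in cols.values())
            if feature in out:
                lo, hi = max(lo, out[feature][0]), min(hi, out[feature][1])
            out[feature] = (lo, hi)
    return out
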