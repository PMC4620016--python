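"""Posterior-based severe-hemorrhage classification and the MT comparison.

Patients are assigned to the class with maximal posterior probability; for
the two-class model the class-1 (severe hemorrhage, SH) posterior is also
mapped onto a graded band scheme, and the resulting SH indicator is
cross-tabulated against the conventional massive-transfusion (MT) rule of
>= 10 RBC units within 24 h.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "BandScheme",
    "default_bands",
    "classify_posteriors",
    "mt_rule",
    "Comparison2x2",
    "compare_sh_mt",
]


@dataclasses.dataclass(frozen=True)
class Band:
    lower: float
    upper: float
    label: str


@dataclasses.dataclass(frozen=True)
class BandScheme:
    """Ordered posterior-probability bands partitioning [0, 1].

    Intervals are half-open [lower, upper), with the top band closed at 1.0.
    """

    bands: tuple

    def __post_init__(self):
        bands = tuple(sorted(self.bands, key=lambda b: b.lower))
        if not bands:
            raise ValueError("band scheme must contain at least one band")
        if bands[0].lower != 0.0 or bands[-1].upper != 1.0:
            raise ValueError("bands must cover [0, 1]")
        for a, b in zip(bands, bands[1:]):
            if abs(a.upper - b.lower) > 1e-12:
                raise ValueError(
                    f"bands must partition [0, 1]: gap/overlap between "
                    f"{a.label!r} and {b.label!r}"
                )
        object.__setattr__(self, "bands", bands)

    def label(self, p: float) -> str:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"posterior probability {p} outside [0, 1]")
        for band in self.bands:
            if band.lower <= p < band.upper:
                return band.label
        return self.bands[-1].label  # p == 1.0


def default_bands() -> BandScheme:
    """The seven-band grading of the class-1 (SH) posterior probability."""
    return BandScheme(
        bands=(
            Band(0.80, 1.00, "Group SH"),
            Band(0.60, 0.80, "Likely group SH"),
            Band(0.55, 0.60, "Doubtful, maybe group SH"),
            Band(0.45, 0.55, "Uncertain"),
            Band(0.40, 0.45, "Doubtful, maybe group non-SH"),
            Band(0.20, 0.40, "Likely group non-SH"),
            Band(0.00, 0.20, "Group non-SH"),
        )
    )


def classify_posteriors(
    posteriors, scheme: BandScheme | None = None
) -> pd.DataFrame:
    """Band labels and a hard SH indicator from class-1 posteriors.

    The hard label is SH iff the posterior exceeds 0.5; a posterior of
    exactly 0.5 falls in the Uncertain band and is conservatively
    hard-assigned non-SH (no unnecessary MT activation).
    """
    p = np.asarray(posteriors, dtype=float)
    if np.any((p < 0) | (p > 1)):
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"posterior probability {bad} outside [0, 1]")
    scheme = scheme or default_bands()
    labels = [scheme.label(float(pi)) for pi in p]
    return pd.DataFrame(
        {"posterior_sh": p, "band_label": labels, "sh": (p > 0.5).astype(int)}
    )


def argmax_classes(posterior_matrix) -> np.ndarray:
    """Hard class labels (1-based) by maximum posterior; for K > 2 the band
    scheme does not apply and only the argmax rule is used."""
    g = np.atleast_2d(np.asarray(posterior_matrix, dtype=float))
    return g.argmax(axis=1) + 1


def mt_rule(rbc_units, threshold: float = 10.0) -> np.ndarray:
    """Conventional massive-transfusion indicator: observed units >= threshold."""
    units = np.asarray(rbc_units, dtype=float)
    if np.any(~np.isfinite(units)):
        raise ValueError("missing or non-finite RBC units")
    return (units >= threshold).astype(int)


@dataclasses.dataclass(frozen=True)
class Comparison2x2:
    """Cross-tabulation of SH status (rows) against MT status (columns).

    ``counts[i, j]`` counts patients with SH == i and MT == j.  Treating SH
    as the reference: sensitivity = P(MT | SH), specificity =
    P(non-MT | non-SH), agreement = concordant / total.
    """

    counts: np.ndarray
    agreement: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "counts": {
                "non_sh_non_mt": int(c[0, 0]),
                "non_sh_mt": int(c[0, 1]),
                "sh_non_mt": int(c[1, 0]),
                "sh_mt": int(c[1, 1]),
            },
            "agreement": self.agreement,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compare_sh_mt(sh: Sequence[int], mt: Sequence[int]) -> Comparison2x2:
    """2x2 comparison of the latent-class SH label against the MT rule."""
    sh = np.asarray(sh, dtype=int)
    mt = np.asarray(mt, dtype=int)
    if sh.shape != mt.shape:
        raise ValueError(
            f"length mismatch: {sh.shape[0]} SH labels vs {mt.shape[0]} MT labels"
        )
    counts = np.zeros((2, 2), dtype=int)
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = int(np.sum((sh == i) & (mt == j)))
    total = counts.sum()
    n_sh = counts[1].sum()
    n_non = counts[0].sum()
    return Comparison2x2(
        counts=counts,
        agreement=float((counts[0, 0] + counts[1, 1]) / total),
        sensitivity=float(counts[1, 1] / n_sh) if n_sh else float("nan"),
        specificity=float(counts[0, 0] / n_non) if n_non else float("nan"),
    )
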