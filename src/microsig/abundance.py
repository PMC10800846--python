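"""Discretization of per-OTU abundances into Absent/Low/Medium/High classes.

Each signature OTU's per-sample count vector is mapped to ordinal abundance
classes relative to its own mean, so abundance can serve as a classification
target. Two schemes exist:

* ``with_absent`` — used whenever at least one sample has a zero count. The
  mean m is taken over the *present* (nonzero) samples; a zero count is
  Absent, a count strictly above m is High, anything else (0 < count <= m)
  is Low. Medium never occurs.
* ``all_present`` — used when every sample carries the OTU. The mean m is
  over all samples; counts strictly above 1.5 m are High, strictly below
  0.5 m are Low, and the closed band [0.5 m, 1.5 m] is Medium. Absent never
  occurs. The three-way split prevents a two-line design from collapsing the
  classes onto the line label.

Thresholds are mean-relative, so the assignment is invariant to rescaling all
counts by a positive constant (sequencing depth does not matter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microsig.containers import InputError

CLASS_ORDER = ("Absent", "Low", "Medium", "High")
CLASS_LETTER = {"Absent": "A", "Low": "L", "Medium": "M", "High": "H"}

#: ordinal step index within each scheme (three steps in either scheme)
_STEPS = {
    "with_absent": {"Absent": 0, "Low": 1, "High": 2},
    "all_present": {"Low": 0, "Medium": 1, "High": 2},
}


@dataclass
class AbundanceClassLabels:
    """Per-sample abundance classes for one OTU, plus the thresholds used."""

    otu_id: str
    labels: pd.Series  # sample id -> class name
    scheme: str  # "with_absent" | "all_present"
    thresholds: dict = field(default_factory=dict)  # mean and cutoffs, count units
    degenerate: bool = False  # fewer than two distinct classes emitted

    @property
    def classes_present(self) -> list[str]:
        present = set(self.labels)
        return [c for c in CLASS_ORDER if c in present]

    def ordinal_steps(self) -> pd.Series:
        """Map classes to ordinal step indices (0, 1, 2) within the scheme."""
        return self.labels.map(_STEPS[self.scheme])

    def letters(self) -> pd.Series:
        return self.labels.map(CLASS_LETTER)


def discretize(counts: pd.Series, otu_id: str = "") -> AbundanceClassLabels:
    """Assign each sample an abundance class for one OTU.

    Parameters
    ----------
    counts : pd.Series
        Non-negative per-sample counts, indexed by sample id.
    otu_id : str
        Identifier recorded in the result.

    Raises
    ------
    InputError
        If every count is zero (no class assignment is possible).
    """
    values = np.asarray(counts, dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        raise InputError(f"invalid counts for OTU {otu_id!r}")
    if (values == 0).all():
        raise InputError(f"OTU {otu_id!r} has all-zero counts; cannot discretize")

    # a value within 1e-9 relative distance of a cutoff is treated as on the
    # cutoff, so rescaled counts (whose rounding can nudge an exact boundary
    # by one ulp) classify identically to the originals
    def above(v, cut):
        return (v > cut) & ~np.isclose(v, cut, rtol=1e-9, atol=0.0)

    def below(v, cut):
        return (v < cut) & ~np.isclose(v, cut, rtol=1e-9, atol=0.0)

    if (values == 0).any():
        scheme = "with_absent"
        m = values[values > 0].mean()
        labels = np.where(values == 0, "Absent", np.where(above(values, m), "High", "Low"))
        thresholds = {"mean_present": m, "high_above": m}
    else:
        scheme = "all_present"
        m = values.mean()
        hi, lo = 1.5 * m, 0.5 * m
        labels = np.where(above(values, hi), "High", np.where(below(values, lo), "Low", "Medium"))
        thresholds = {"mean": m, "high_above": hi, "low_below": lo}

    series = pd.Series(labels, index=counts.index, name=otu_id or None)
    return AbundanceClassLabels(
        otu_id=otu_id,
        labels=series,
        scheme=scheme,
        thresholds=thresholds,
        degenerate=series.nunique() < 2,
    )


def discretize_table(counts: pd.DataFrame, otu_ids=None) -> dict[str, AbundanceClassLabels]:
    """Discretize several OTUs of a samples x OTUs count table at once."""
    otu_ids = list(counts.columns) if otu_ids is None else list(otu_ids)
    return {o: discretize(counts[o], otu_id=o) for o in otu_ids}


def class_grid(results: dict[str, AbundanceClassLabels]) -> pd.DataFrame:
    """OTUs x samples grid of single-letter class codes (A/L/M/H)."""
    rows = {o: r.letters() for o, r in results.items()}
    return pd.DataFrame(rows).T
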