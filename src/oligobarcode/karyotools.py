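"""Karyotype measurement statistics.

Implements the chromosome-measurement arithmetic used to compare metaphase
karyotypes between species: per-cell relative chromosome length
(100 x length / total length), arm ratio (long arm / short arm), Pearson
correlation of paired per-cell series between species, and the three-band
physical-distance-ratio statistic (d(band1,band2)/d(band2,band3)) with a
two-sample t-test.  All statistics are scale invariant, so measurements may
be in micrometers or pixels.

Input measurements are rows of (species, cell_id, chrom, short_arm,
long_arm); homolog duplicates within a cell are averaged before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MEASUREMENT_COLUMNS = ("species", "cell_id", "chrom", "short_arm", "long_arm")


def normalize_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce short_arm <= long_arm and average homolog duplicates."""
    df = df.copy()
    if (df["short_arm"] <= 0).any() or (df["long_arm"] <= 0).any():
        raise ValueError("arm lengths must be positive")
    swap = df["short_arm"] > df["long_arm"]
    if swap.any():
        s = df.loc[swap, "short_arm"].copy()
        df.loc[swap, "short_arm"] = df.loc[swap, "long_arm"]
        df.loc[swap, "long_arm"] = s
    return (
        df.groupby(["species", "cell_id", "chrom"], as_index=False)[
            ["short_arm", "long_arm"]
        ].mean()
    )


def relative_length_cell(cell: pd.DataFrame) -> pd.Series:
    """Per-chromosome relative length (%) within one complete cell."""
    total = (cell["short_arm"] + cell["long_arm"]).sum()
    rel = 100.0 * (cell["short_arm"] + cell["long_arm"]) / total
    return pd.Series(rel.to_numpy(), index=cell["chrom"].to_numpy())


def relative_length(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of relative length per chromosome, per species.

    Cells missing any chromosome of their species' full complement are
    excluded with a warning.  Returns columns
    (species, chrom, rel_length_mean, rel_length_sd, n_cells).
    """
    df = normalize_measurements(measurements)
    out = []
    for species, sdf in df.groupby("species"):
        complement = set(sdf["chrom"].unique())
        per_cell = []
        for cell_id, cdf in sdf.groupby("cell_id"):
            if set(cdf["chrom"]) != complement:
                warnings.warn(
                    f"cell {species}/{cell_id} incomplete: excluded", stacklevel=2
                )
                continue
            per_cell.append(relative_length_cell(cdf))
        if not per_cell:
            continue
        mat = pd.DataFrame(per_cell)
        for chrom in sorted(complement):
            vals = mat[chrom]
            out.append(
                (species, chrom, float(vals.mean()),
                 float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, len(vals))
            )
    return pd.DataFrame(
        out, columns=["species", "chrom", "rel_length_mean", "rel_length_sd", "n_cells"]
    )


def arm_ratio(short_arm: float, long_arm: float, mode: str = "long_over_short") -> float:
    """Arm ratio of one measurement.

    Default is long/short (>= 1 by definition); ``short_over_long`` returns
    the reciprocal, provided because published tables are seen using either
    convention.
    """
    if short_arm <= 0 or long_arm <= 0:
        raise ValueError("arm lengths must be positive")
    lo, hi = sorted((short_arm, long_arm))
    return hi / lo if mode == "long_over_short" else lo / hi


def arm_ratio_table(measurements: pd.DataFrame, mode: str = "long_over_short") -> pd.DataFrame:
    df = normalize_measurements(measurements)
    r = df.apply(lambda row: arm_ratio(row["short_arm"], row["long_arm"], mode), axis=1)
    df = df.assign(ratio=r)
    g = df.groupby(["species", "chrom"], as_index=False)["ratio"].agg(["mean", "std", "size"])
    g = g.rename(columns={"mean": "arm_ratio_mean", "std": "arm_ratio_sd", "size": "n"})
    g["arm_ratio_sd"] = g["arm_ratio_sd"].fillna(0.0)
    return g


def chromosome_correlation(series_a, series_b) -> float:
    """Pearson r between paired per-cell series for one homolog pairing.

    Returns NaN (with a warning) when either series has zero variance.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must be paired with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class BandTriplet:
    species: str
    cell_id: str
    chrom: str
    p1: float
    p2: float
    p3: float

    def __post_init__(self):
        if not (self.p1 < self.p2 < self.p3):
            raise ValueError("band positions must satisfy p1 < p2 < p3")


def band_distance_ratio(t: BandTriplet) -> float:
    """(p2 - p1) / (p3 - p2): the ratio of the two inter-band distances."""
    return (t.p2 - t.p1) / (t.p3 - t.p2)


def compare_ratios(group1, group2, equal_var: bool = False):
    """Two-sample t-test on band-distance ratios between two groups.

    Groups are iterables of ``BandTriplet`` or of precomputed ratios.
    Welch's unequal-variance test by default (``equal_var=True`` gives the
    classic pooled test); two-tailed p, no multiplicity adjustment.
    Returns ``(t_statistic, p_value)``.
    """

    def ratios(group):
        vals = []
        for g in group:
            vals.append(band_distance_ratio(g) if isinstance(g, BandTriplet) else float(g))
        return np.array(vals, dtype=float)

    r1, r2 = ratios(group1), ratios(group2)
    if r1.size < 2 or r2.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(r1, r2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def karyotype_table(
    measurements: pd.DataFrame,
    pairing: dict = None,
    mode: str = "long_over_short",
) -> pd.DataFrame:
    """Relative length and arm ratio summary, optionally with between-species
    Pearson coefficients for a given chromosome pairing.

    ``pairing`` maps (species_a_chrom -> species_b_chrom) for exactly two
    species in the input; the coefficient correlates per-cell chromosome
    lengths across cells (paired by cell order).
    """
    rel = relative_length(measurements)
    ratio = arm_ratio_table(measurements, mode=mode)
    table = rel.merge(ratio, on=["species", "chrom"])
    if pairing:
        species = sorted(measurements["species"].unique())
        if len(species) != 2:
            raise ValueError("pairing requires exactly two species")
        df = normalize_measurements(measurements)
        df["length"] = df["short_arm"] + df["long_arm"]
        coeffs = {}
        for ca, cb in pairing.items():
            a = df[(df["species"] == species[0]) & (df["chrom"] == ca)]
            b = df[(df["species"] == species[1]) & (df["chrom"] == cb)]
            a = a.sort_values("cell_id")["length"].to_numpy()
            b = b.sort_values("cell_id")["length"].to_numpy()
            n = min(a.size, b.size)
            coeffs[ca] = (
                chromosome_correlation(a[:n], b[:n]) if n >= 3 else float("nan")
            )
        table["pearson_r"] = [
            coeffs.get(c, float("nan")) if s == species[0] else float("nan")
            for s, c in zip(table["species"], table["chrom"])
        ]
    return table
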