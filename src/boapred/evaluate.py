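"""Validation machinery: splitting, grouping, predictive ability, bias.

The reference/validation split follows a birth-year threshold with a
sire-group co-assignment rule: animals born after the threshold start in
validation, and for every sire with genotyped offspring the whole group
(sire plus all offspring) moves to validation when *strictly more than
half* of the offspring were born after the threshold, otherwise to
reference.  Animals without a known sire keep the year rule.

Predictive ability is the Pearson correlation between adjusted
phenotypes and PGM in the validation set; the dispersion slope is the
OLS slope of adjusted phenotype on PGM (slopes below 1 flag
overdispersed, i.e. inflated, predictions).  Method comparisons use a
paired nonparametric bootstrap: one shared resample of validation
indices per replicate across all methods, a paired t-test on the
replicate-level predictive abilities, and a Bonferroni correction over
the pairwise comparisons within an animal group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Group labels for the main-breed-proportion intervals, in order.
GROUP_LABELS = ("<25%", "25-50%", "50-85%", ">=85%")
_GROUP_EDGES = (0.25, 0.50, 0.85)


@dataclass
class SplitResult:
    """Reference/validation partition with a per-animal rationale code."""

    reference: list[str]
    validation: list[str]
    rationale: dict[str, str]  # animal -> 'year' | 'sire_group'


def split_reference_validation(
    pedigree: pd.DataFrame, threshold_year: int = 2018
) -> SplitResult:
    """Year-threshold split with strict-majority sire-group co-assignment."""
    ped = pedigree
    missing = ped.loc[ped["birth_year"].isna(), "animal"].tolist()
    if missing:
        raise ValueError(f"missing birth years for animals: {missing}")
    year = dict(zip(ped["animal"], ped["birth_year"].astype(int)))
    in_validation = {a: y > threshold_year for a, y in year.items()}
    rationale = {a: "year" for a in year}

    has_sire = ped["sire"].astype(str).str.len() > 0
    for sire, group in sorted(ped[has_sire].groupby("sire")):
        offspring = group["animal"].tolist()
        late = sum(year[a] > threshold_year for a in offspring)
        to_validation = late * 2 > len(offspring)  # strictly more than half
        members = offspring + ([sire] if sire in year else [])
        for a in members:
            in_validation[a] = to_validation
            rationale[a] = "sire_group"
    reference = [a for a in year if not in_validation[a]]
    validation = [a for a in year if in_validation[a]]
    return SplitResult(reference=reference, validation=validation, rationale=rationale)


def group_by_main_breed_proportion(
    X: np.ndarray, main_breed_idx: Sequence[int] = (0, 1)
) -> np.ndarray:
    """Group labels from the summed GBP of the main breeds.

    Half-open intervals [0, 0.25), [0.25, 0.50), [0.50, 0.85) and the
    closed top interval [0.85, 1]; together they partition [0, 1].
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("GBP rows must sum to 1")
    main = X[:, list(main_breed_idx)].sum(axis=1)
    idx = np.digitize(main, _GROUP_EDGES, right=False)
    return np.asarray(GROUP_LABELS)[idx]


def predictive_ability(y_star: np.ndarray, pgm: np.ndarray) -> float:
    """Pearson correlation between adjusted phenotypes and PGM."""
    y = np.asarray(y_star, float)
    p = np.asarray(pgm, float)
    if y.size != p.size or y.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(y).all() and np.isfinite(p).all()):
        raise ValueError("inputs must be finite")
    return float(np.corrcoef(y, p)[0, 1])


def dispersion_slope(y_star: np.ndarray, pgm: np.ndarray) -> float:
    """OLS slope of adjusted phenotype on PGM (the bias measure)."""
    y = np.asarray(y_star, float)
    p = np.asarray(pgm, float)
    vp = np.var(p)
    if vp == 0:
        raise ValueError("PGM has zero variance; slope undefined")
    return float(np.cov(y, p, ddof=1)[0, 1] / np.var(p, ddof=1))


def _bootstrap_r(y: np.ndarray, pgms: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Predictive ability per replicate (rows of idx) and method."""
    yb = y[idx]  # (n_boot, n)
    yc = yb - yb.mean(axis=1, keepdims=True)
    ysd = np.sqrt((yc**2).sum(axis=1))
    out = np.empty((idx.shape[0], pgms.shape[0]))
    for j in range(pgms.shape[0]):
        pb = pgms[j][idx]
        pc = pb - pb.mean(axis=1, keepdims=True)
        psd = np.sqrt((pc**2).sum(axis=1))
        out[:, j] = (yc * pc).sum(axis=1) / (ysd * psd)
    return out


def bootstrap_compare(
    y_star: np.ndarray,
    pgm_by_method: Mapping[str, np.ndarray],
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired bootstrap comparison of predictive abilities across methods.

    One index resample per replicate is shared across all methods, the
    per-replicate predictive abilities are compared with a two-tailed
    paired t-test for every method pair, and p-values are Bonferroni-
    adjusted over the number of pairs.  Also reports each method's
    bootstrap standard error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y = np.asarray(y_star, float)
    methods = list(pgm_by_method)
    pgms = np.stack([np.asarray(pgm_by_method[mth], float) for mth in methods])
    if pgms.shape[1] != y.size:
        raise ValueError("all methods must share the same validation animals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(n_boot, y.size))
    r = _bootstrap_r(y, pgms, idx)
    pairs = list(combinations(range(len(methods)), 2))
    rows = []
    for a, b in pairs:
        d = r[:, a] - r[:, b]
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(r[:, a], r[:, b])
        rows.append(
            {
                "method_a": methods[a],
                "method_b": methods[b],
                "mean_diff": float(d.mean()),
                "t_stat": float(t),
                "p_raw": float(p),
                "p_bonferroni": bonferroni(float(p), len(pairs)),
                "n_comparisons": len(pairs),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bootstrap_r_mean"] = dict(zip(methods, r.mean(axis=0)))
    out.attrs["bootstrap_r_se"] = dict(zip(methods, r.std(axis=0, ddof=1)))
    return out


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: min(1, p * n)."""
    return min(1.0, p_raw * n_comparisons)


def evaluation_report(
    y_star: np.ndarray,
    pgm_by_method: Mapping[str, np.ndarray],
    groups: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-group predictive abilities, slopes and pairwise comparisons.

    Returns ``{'summary': ..., 'comparisons': ...}``.  The summary has
    one row per (group, method) with predictive ability, its bootstrap
    standard error and the dispersion slope; comparisons are Bonferroni-
    corrected within each group.
    """
    y = np.asarray(y_star, float)
    if groups is None:
        groups = np.asarray(["All"] * y.size)
    groups = np.asarray(groups)
    summary_rows = []
    comp_frames = []
    for gname in pd.unique(groups):
        sel = groups == gname
        if sel.sum() < 3:
            continue
        sub = {mth: np.asarray(p, float)[sel] for mth, p in pgm_by_method.items()}
        comp = bootstrap_compare(y[sel], sub, n_boot=n_boot, seed=seed)
        comp.insert(0, "group", gname)
        comp_frames.append(comp)
        for mth, pgm in sub.items():
            summary_rows.append(
                {
                    "group": gname,
                    "method": mth,
                    "n": int(sel.sum()),
                    "predictive_ability": predictive_ability(y[sel], pgm),
                    "se": comp.attrs["bootstrap_r_se"][mth],
                    "slope": dispersion_slope(y[sel], pgm),
                }
            )
    return {
        "summary": pd.DataFrame(summary_rows),
        "comparisons": pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(),
    }
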