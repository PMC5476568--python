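"""Between-group inference for topographic connectivity summaries.

Covers the full statistical surface of the pipeline:

* unpaired Wilcoxon rank-sum tests (exact enumeration at small n, normal
  approximation with tie correction otherwise), Benjamini–Hochberg FDR and
  Cohen's d for the 21 ROI-pair values;
* Monte-Carlo label-permutation tests for distance profiles;
* the two-stage seed analysis (per-connection rank-sum tests summarized per
  ROI-external electrode by the median p-value and FDR counts);
* demographic comparisons from printed summary statistics (pooled-variance
  t-tests and the Pearson chi-squared test for the sex contingency table).

Sign convention: throughout, a *positive* sign means controls rank above
patients (hypoconnectivity in patients), so seed maps plot patient deficits
as positive scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .montage import Montage, ROI_IDS
from .topo import roi_pair_labels

__all__ = [
    "ALPHA",
    "SEED_SCORE_THRESHOLD",
    "RankSumResult",
    "SeedMap",
    "ranksum_test",
    "fdr_bh",
    "cohens_d",
    "roi_pair_comparison",
    "permutation_profile_test",
    "seed_analysis",
    "second_stage_seeds",
    "summary_ttest",
    "chisq_2x2",
    "compare_demographics",
    "reference_demographics",
]

ALPHA = 0.05
#: Seed-map scores beyond +/- this value correspond to median p < 0.05.
SEED_SCORE_THRESHOLD = -math.log10(ALPHA)  # ~1.3

_EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    W: float  # rank sum of the first sample
    sign: int  # sign of W minus its null expectation
    p: float
    exact: bool


def ranksum_test(a, b) -> RankSumResult:
    """Two-sided unpaired Wilcoxon rank-sum test.

    Exact enumeration of the permutation distribution (on midranks) when the
    pooled sample has at most 12 observations; otherwise the normal
    approximation with tie correction.  The sign is that of the observed
    rank sum of ``a`` minus its null expectation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    n = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:na].sum())
    ew = na * (n + 1) / 2.0
    delta = w - ew
    sign = int(np.sign(delta))
    if n <= _EXACT_MAX_N:
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n), na):
            total += 1
            if abs(ranks[list(comb)].sum() - ew) >= abs(delta) - 1e-12:
                hits += 1
        return RankSumResult(W=w, sign=sign, p=hits / total, exact=True)
    # normal approximation with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return RankSumResult(W=w, sign=0, p=1.0, exact=False)
    z = delta / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankSumResult(W=w, sign=sign, p=min(1.0, p), exact=False)


def fdr_bh(pvals, q: float = ALPHA) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation.

    Returns ``NaN`` when the pooled SD is zero and the means differ;
    0 for identical constant samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    diff = a.mean() - b.mean()
    pooled = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / pooled)


def roi_pair_comparison(
    vectors: pd.DataFrame, groups: pd.Series, q: float = ALPHA
) -> pd.DataFrame:
    """Compare the 21 ROI-pair connectivity values between groups.

    Parameters
    ----------
    vectors
        Per-subject ROI-pair means, one row per subject, one column per
        ROI pair (as produced by :func:`infoshare.topo.roi_pair_means`).
    groups
        Subject-id-indexed series with values ``"patient"``/``"control"``.

    Returns
    -------
    One row per ROI pair: group means/SDs, rank-sum ``W`` (controls first),
    sign (positive = hypoconnectivity in patients), raw two-sided p,
    raw/FDR significance flags at ``q``, and Cohen's d (controls minus
    patients, pooled SD).
    """
    groups = groups.loc[vectors.index]
    pat = vectors.loc[groups == "patient"]
    ctl = vectors.loc[groups == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("each group needs at least two subjects")
    rows = []
    for col in vectors.columns:
        r = ranksum_test(ctl[col].to_numpy(), pat[col].to_numpy())
        rows.append(
            {
                "roi_pair": col,
                "patient_mean": pat[col].mean(),
                "patient_sd": pat[col].std(ddof=1),
                "control_mean": ctl[col].mean(),
                "control_sd": ctl[col].std(ddof=1),
                "W": r.W,
                "sign": r.sign,
                "p": r.p,
                "cohens_d": cohens_d(ctl[col], pat[col]),
            }
        )
    out = pd.DataFrame(rows).set_index("roi_pair")
    out["raw_significant"] = out["p"] <= q
    out["fdr_significant"] = fdr_bh(out["p"].to_numpy(), q)
    return out


def permutation_profile_test(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    bootstrap: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo group test on per-subject distance-bin means.

    The per-bin statistic is the absolute difference of group means; the
    null is built by shuffling group labels across subjects, all bins
    sharing each shuffle.  P-values use the add-one estimator
    ``(exceedances + 1) / (n_perm + 1)`` and are therefore bounded below by
    ``1/(n_perm + 1)``.  With ``bootstrap=True`` the null draws subjects
    with replacement from the pooled sample instead of permuting labels.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same bins")
    # canonicalize so that swapping the two groups yields identical draws
    if a.shape[0] > b.shape[0]:
        a, b = b, a
    na = a.shape[0]
    pooled = np.vstack([a, b])
    n = pooled.shape[0]
    observed = np.abs(a.mean(axis=0) - b.mean(axis=0))
    rng = np.random.default_rng(seed)
    if bootstrap:
        idx = rng.integers(0, n, size=(n_perm, n))
    else:
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
    drawn = pooled[idx]  # (n_perm, n, n_bins)
    null = np.abs(
        drawn[:, :na].mean(axis=1) - drawn[:, na:].mean(axis=1)
    )
    exceed = (null >= observed[None, :] - 1e-15).sum(axis=0)
    pvals = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame(
        {"observed_diff": a.mean(axis=0) - b.mean(axis=0), "p": pvals}
    )


@dataclass(frozen=True)
class SeedMap:
    """Summary of one seed set's connectivity differences.

    ``per_electrode`` is indexed by ROI-external electrode label with
    columns ``median_p``, ``signed_score`` (sign times -log10 median p;
    beyond +/-1.3 means median p < 0.05) and ``n_significant`` (seed
    connections surviving FDR).  ``connections`` holds the underlying
    per-connection tests.
    """

    seeds: tuple[str, ...]
    per_electrode: pd.DataFrame
    connections: pd.DataFrame


def seed_analysis(
    matrices: np.ndarray,
    groups: np.ndarray | pd.Series,
    montage: Montage,
    seeds: str | list[str],
    q: float = ALPHA,
) -> SeedMap:
    """Test every seed-to-external connection between groups.

    Parameters
    ----------
    matrices
        Stacked per-subject connectivity matrices ``(n_subjects, C, C)`` in
        montage channel order.
    groups
        Length-``n_subjects`` labels (``"patient"``/``"control"``).
    seeds
        A ROI id (its electrodes become the seeds and all other channels
        the ROI-external electrodes) or an explicit list of seed channels.
    """
    mats = np.asarray(matrices, dtype=float)
    grp = np.asarray(groups)
    if isinstance(seeds, str):
        seed_labels = list(montage.roi_channels(seeds))
    else:
        seed_labels = list(seeds)
    if not seed_labels:
        raise ValueError("empty seed set")
    external = [lb for lb in montage.labels if lb not in seed_labels]
    if not external:
        raise ValueError("no ROI-external electrodes")
    ctl = np.flatnonzero(grp == "control")
    pat = np.flatnonzero(grp == "patient")
    rows = []
    for s in seed_labels:
        si = montage.index(s)
        for e in external:
            ei = montage.index(e)
            vals = mats[:, si, ei]
            r = ranksum_test(vals[ctl], vals[pat])
            rows.append(
                {"seed": s, "external": e, "W": r.W, "sign": r.sign,
                 "delta": r.W - len(ctl) * (len(ctl) + len(pat) + 1) / 2.0,
                 "p": r.p}
            )
    conn = pd.DataFrame(rows)
    conn["fdr_significant"] = fdr_bh(conn["p"].to_numpy(), q)
    per = []
    for e, sub in conn.groupby("external", sort=False):
        med_p = float(sub["p"].median())
        sign = int(np.sign(sub["delta"].median()))
        score = sign * (-math.log10(max(med_p, 1e-300)))
        per.append(
            {"external": e, "median_p": med_p, "sign": sign,
             "signed_score": score,
             "n_significant": int(sub["fdr_significant"].sum())}
        )
    per_df = pd.DataFrame(per).set_index("external").loc[external]
    return SeedMap(seeds=tuple(seed_labels), per_electrode=per_df,
                   connections=conn)


def second_stage_seeds(
    map_left: SeedMap,
    map_right: SeedMap,
    montage: Montage,
    top_n: int = 5,
    threshold: float = SEED_SCORE_THRESHOLD,
) -> dict[str, tuple[str, ...]]:
    """Select the next-stage seed electrodes from two frontal seed maps.

    The two maps' signed scores are averaged per shared ROI-external
    electrode; within every ROI containing at least one electrode whose
    averaged score exceeds ``threshold`` (patient hypoconnectivity), the
    ``top_n`` highest-scoring electrodes are returned as that region's new
    seed set.  Rank ties break deterministically by channel label.

    Returns an empty dict when no region reaches the threshold.
    """
    shared = [e for e in map_left.per_electrode.index
              if e in map_right.per_electrode.index]
    if not shared:
        raise ValueError("seed maps share no external electrodes")
    avg = (
        map_left.per_electrode.loc[shared, "signed_score"]
        + map_right.per_electrode.loc[shared, "signed_score"]
    ) / 2.0
    out: dict[str, tuple[str, ...]] = {}
    for roi in ROI_IDS:
        members = [e for e in shared if montage.roi_of[e] == roi]
        if not members:
            continue
        scores = avg.loc[members]
        if scores.max() <= threshold:
            continue
        ranked = sorted(members, key=lambda e: (-scores[e], e))
        out[roi] = tuple(ranked[:top_n])
    return out


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        return float("inf"), df, float("nan")
    t = (mean1 - mean2) / math.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared test (1 df, no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def _format_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"


def compare_demographics(table: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons from a printed summary table.

    ``table`` has one row per variable with columns ``variable``, ``kind``
    (``"continuous"``: mean/sd/n per group, or ``"counts"``: a 2x2 sex
    table as ``a_pos/a_neg/b_pos/b_neg``).  Continuous rows get the
    pooled-variance t-test, count rows the Pearson chi-squared test; the
    ``p_display`` column rounds to typical publication precision.
    """
    rows = []
    for _, row in table.iterrows():
        try:
            if row["kind"] == "continuous":
                t, df, p = summary_ttest(
                    row["mean_a"], row["sd_a"], int(row["n_a"]),
                    row["mean_b"], row["sd_b"], int(row["n_b"]),
                )
                stat = t
            elif row["kind"] == "counts":
                stat, p = chisq_2x2(
                    [[row["a_pos"], row["a_neg"]],
                     [row["b_pos"], row["b_neg"]]]
                )
            else:
                raise ValueError(f"unknown kind {row['kind']!r}")
        except (KeyError, ValueError, TypeError) as exc:
            rows.append({"variable": row.get("variable", "?"),
                         "statistic": float("nan"), "p": float("nan"),
                         "p_display": "", "error": str(exc)})
            continue
        rows.append({"variable": row["variable"], "statistic": stat,
                     "p": p, "p_display": _format_p(p), "error": ""})
    return pd.DataFrame(rows)


def reference_demographics() -> dict[str, pd.DataFrame]:
    """Printed demographic/neuropsychological summaries of the dementia
    study this pipeline emulates (patients listed first in each arm).

    Two arms: ``"bvftd"`` (13 patients vs 25 matched controls) and ``"ad"``
    (13 patients vs 18 matched controls).  Values are means (SDs) as
    published; the sex rows are female:male counts.
    """

    def cont(name, ma, sa, na, mb, sb, nb):
        return {"variable": name, "kind": "continuous",
                "mean_a": ma, "sd_a": sa, "n_a": na,
                "mean_b": mb, "sd_b": sb, "n_b": nb}

    bvftd = pd.DataFrame([
        {"variable": "sex", "kind": "counts",
         "a_pos": 7, "a_neg": 6, "b_pos": 15, "b_neg": 10},
        cont("age", 69.31, 10.55, 13, 70.40, 5.22, 25),
        cont("education", 15.0, 3.34, 13, 16.96, 3.47, 25),
        cont("ace_total", 70.77, 10.66, 13, 92.17, 6.84, 25),
        cont("ravlt_immediate", 24.23, 8.87, 13, 42.89, 10.07, 25),
        cont("ravlt_delayed", 3.69, 2.81, 13, 7.28, 3.32, 25),
        cont("ifs_total", 15.65, 4.39, 13, 24.94, 2.25, 25),
    ])
    ad = pd.DataFrame([
        {"variable": "sex", "kind": "counts",
         "a_pos": 11, "a_neg": 2, "b_pos": 12, "b_neg": 6},
        cont("age", 75.62, 9.42, 13, 72.28, 4.42, 18),
        cont("education", 12.77, 7.60, 13, 15.94, 3.35, 18),
        cont("ace_total", 78.62, 11.86, 13, 93.12, 6.06, 18),
        cont("ravlt_immediate", 27.46, 8.25, 13, 42.68, 10.19, 18),
        cont("ravlt_delayed", 1.31, 3.12, 13, 7.11, 3.38, 18),
        cont("ifs_total", 17.77, 7.57, 13, 25.40, 2.26, 18),
    ])
    return {"bvftd": bvftd, "ad": ad}
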