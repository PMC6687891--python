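"""Region-level statistics over fitted variant effects.

Covers replicate reproducibility, the run-length permutation test for
positional clustering of significant effects, and rank-sum / binomial
contrasts between variant classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

_LABEL_CODES = {"nonsignificant": 0, "activating": 1, "repressing": -1}


def order_track(labelled: pd.DataFrame) -> pd.DataFrame:
    """Sort variants by (position, alt order A<C<G<T<deletion)."""
    key = labelled["alt"].map(lambda a: 4 if a == "" else "ACGT".index(a))
    return (
        labelled.assign(_alt_order=key)
        .sort_values(["position", "_alt_order"], kind="mergesort")
        .drop(columns="_alt_order")
        .reset_index(drop=True)
    )


def replicate_reproducibility(
    estimates_a: pd.DataFrame, estimates_b: pd.DataFrame
) -> dict:
    """Pearson correlation of standardized effects between two fits.

    Standardized effect = log2_effect / std_error, following the
    reproducibility measure used for replicate comparison; the plain
    effect correlation is reported alongside.
    """
    a = estimates_a.set_index(["position", "ref", "alt"])
    b = estimates_b.set_index(["position", "ref", "alt"])
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared variants; need >= 3")
    a, b = a.loc[shared], b.loc[shared]
    r_std, _ = stats.pearsonr(
        a["log2_effect"] / a["std_error"], b["log2_effect"] / b["std_error"]
    )
    r_effect, _ = stats.pearsonr(a["log2_effect"], b["log2_effect"])
    return {"r_standardized": float(r_std), "r_effect": float(r_effect), "n_shared": len(shared)}


def _run_lengths(codes: np.ndarray, directional: bool = True) -> np.ndarray:
    """Lengths of maximal runs of identical nonzero label codes.

    Nonsignificant entries (code 0) terminate runs but form none. With
    ``directional=False`` activating/repressing are pooled into one
    significant state before run construction.
    """
    if not directional:
        codes = (codes != 0).astype(np.int8)
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    boundaries = np.flatnonzero(np.diff(codes) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [n]))
    lengths = ends - starts
    return lengths[codes[starts] != 0]


def clustering_test(
    track: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int | None = 0,
    directional: bool = True,
) -> dict:
    """Permutation run-length test for clustering of significant variants.

    The statistic is the multiset of run lengths of maximal same-label
    runs (activating / repressing) along the ordered track; the null
    pools run lengths from ``n_shuffles`` uniform label permutations.
    The p-value is a one-sided rank-sum test (with continuity
    correction) of observed vs pooled null run lengths.
    """
    ordered = order_track(track)
    codes = ordered["label"].map(_LABEL_CODES).to_numpy(dtype=np.int8)
    observed = _run_lengths(codes, directional)
    if observed.size == 0:
        return {"p_value": None, "observed_runs": [], "reason": "no significant variants"}

    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    shuffled = codes.copy()
    for _ in range(n_shuffles):
        rng.shuffle(shuffled)
        null.append(_run_lengths(shuffled, directional))
    null_pool = np.concatenate(null) if null else np.empty(0)
    if null_pool.size == 0 or np.ptp(np.concatenate((observed, null_pool))) == 0:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(
            observed, null_pool, alternative="greater", use_continuity=True, method="asymptotic"
        )
    return {
        "p_value": float(p),
        "observed_runs": observed.tolist(),
        "observed_mean_run": float(observed.mean()),
        "null_mean_run": float(null_pool.mean()) if null_pool.size else float("nan"),
        "n_shuffles": n_shuffles,
    }


def hodges_lehmann_shift(x: np.ndarray, y: np.ndarray, max_pairs: int = 5_000_000) -> float:
    """Median of pairwise differences x_i - y_j (location-shift estimate)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size * y.size <= max_pairs:
        return float(np.median(np.subtract.outer(x, y)))
    rng = np.random.default_rng(0)
    xi = rng.integers(0, x.size, size=max_pairs)
    yi = rng.integers(0, y.size, size=max_pairs)
    return float(np.median(x[xi] - y[yi]))


def rank_sum_contrast(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Two-sided rank-sum test with continuity correction + HL shift."""
    values_a, values_b = np.asarray(values_a), np.asarray(values_b)
    stat, p = stats.mannwhitneyu(
        values_a, values_b, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "location_shift": hodges_lehmann_shift(values_a, values_b),
        "n_a": int(values_a.size),
        "n_b": int(values_b.size),
    }


def binomial_contrast(k: int, n: int, p_null: float = 0.5) -> dict:
    """Exact two-sided binomial test of k successes in n trials."""
    result = stats.binomtest(k, n, p_null)
    return {"k": k, "n": n, "p_null": p_null, "p_value": float(result.pvalue),
            "proportion": k / n if n else float("nan")}


def class_comparisons(labelled: pd.DataFrame) -> dict:
    """Standard contrasts over a labelled effects table.

    Effect-size contrasts (rank-sum + Hodges-Lehmann shift) between
    transitions and transversions and between SNVs and 1-bp deletions;
    a binomial test of the activating/repressing split against 0.5.
    """
    report: dict = {}
    abs_effect = labelled["log2_effect"].abs()
    vclass = labelled["variant"].map(lambda v: v.vclass) if "variant" in labelled else None
    if vclass is None:
        raise ValueError("labelled table must carry a 'variant' column")

    ts = abs_effect[vclass == "transition"].to_numpy()
    tv = abs_effect[vclass == "transversion"].to_numpy()
    if ts.size and tv.size:
        # transversions reported first so a positive shift means larger
        # transversion effects
        report["transversion_vs_transition"] = rank_sum_contrast(tv, ts)
    else:
        warnings.warn("empty transition or transversion class; contrast skipped")

    dels = abs_effect[vclass == "deletion_1bp"].to_numpy()
    snvs = abs_effect[vclass != "deletion_1bp"].to_numpy()
    if dels.size and snvs.size:
        report["deletion_vs_snv"] = rank_sum_contrast(dels, snvs)

    n_act = int((labelled["label"] == "activating").sum())
    n_rep = int((labelled["label"] == "repressing").sum())
    if n_act + n_rep:
        report["activating_vs_repressing"] = binomial_contrast(n_act, n_act + n_rep)
    report["counts"] = {
        "transition": int(ts.size),
        "transversion": int(tv.size),
        "deletion_1bp": int(dels.size),
        "activating": n_act,
        "repressing": n_rep,
    }
    return report
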