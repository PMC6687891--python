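"""Per-variant expression effects by multiple linear regression.

The response is log2(RNA count) over (replicate, tag) rows. Predictors
are per-replicate log2(DNA count) columns (zero off-replicate), a single
intercept, and one binary indicator column per variant. The coefficient
of a variant's indicator column is its log2 expression effect relative
to wild type; OLS t-statistics give (admittedly anti-conservative)
p-values and confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .assignment import TagAssignment
from .core import Variant

_DENSE_LIMIT = 2_000_000  # rows*cols below which a dense design is used


def _variant_sort_key(v: Variant):
    # position, then alt order A < C < G < T < deletion
    return (v.position, 4 if v.is_deletion else "ACGT".index(v.alt))


@dataclass
class DesignMatrix:
    X: np.ndarray | sp.csr_matrix
    y: np.ndarray
    dna_replicates: list[int]          # replicate label per DNA column
    variants: list[Variant]            # variant per indicator column, after DNA + intercept
    row_tags: np.ndarray               # tag per row
    row_replicates: np.ndarray         # replicate per row
    n_obs: np.ndarray                  # rows carrying each variant
    n_distinct_tags: np.ndarray        # distinct tags carrying each variant

    @property
    def n_fixed(self) -> int:
        """DNA columns + intercept preceding the variant block."""
        return len(self.dna_replicates) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


class EmptyDesignError(ValueError):
    pass


class FitError(RuntimeError):
    pass


def build_design(
    counts: pd.DataFrame,
    assignment: TagAssignment,
    mode: str = "combined",
) -> DesignMatrix:
    """Assemble the regression design from joined counts and an assignment.

    Rows are (replicate, tag) with both RNA and DNA observed; tags that
    are disqualified (insertion / multi-bp deletion / ...) or absent
    from the assignment contribute no rows. ``single_replicate`` mode
    requires exactly one replicate and yields one DNA column.
    """
    if mode not in ("combined", "single_replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    good = assignment.good_tags()
    rows = counts[counts["tag"].isin(good.keys())].reset_index(drop=True)
    if rows.empty:
        raise EmptyDesignError("no usable (replicate, tag) rows")
    replicates = sorted(rows["replicate"].unique())
    if mode == "single_replicate" and len(replicates) != 1:
        raise ValueError(f"single_replicate mode with {len(replicates)} replicates present")

    n = len(rows)
    y = np.log2(rows["rna_count"].to_numpy(dtype=float))
    log_dna = np.log2(rows["dna_count"].to_numpy(dtype=float))
    rep_of_row = rows["replicate"].to_numpy()
    tags = rows["tag"].to_numpy()

    # variants observed on at least one included row, in track order
    variant_rows: dict[Variant, list[int]] = {}
    tag_variants = {t: good[t].variants for t in rows["tag"].unique()}
    for i, tag in enumerate(tags):
        for v in tag_variants[tag]:
            variant_rows.setdefault(v, []).append(i)
    variants = sorted(variant_rows, key=_variant_sort_key)

    n_fixed = len(replicates) + 1
    n_cols = n_fixed + len(variants)
    data, row_idx, col_idx = [], [], []
    for c, rep in enumerate(replicates):
        mask = rep_of_row == rep
        idx = np.nonzero(mask)[0]
        row_idx.append(idx)
        col_idx.append(np.full(idx.size, c))
        data.append(log_dna[idx])
    row_idx.append(np.arange(n))
    col_idx.append(np.full(n, len(replicates)))
    data.append(np.ones(n))

    n_obs = np.empty(len(variants), dtype=np.int64)
    n_distinct = np.empty(len(variants), dtype=np.int64)
    for c, v in enumerate(variants):
        idx = np.asarray(variant_rows[v])
        row_idx.append(idx)
        col_idx.append(np.full(idx.size, n_fixed + c))
        data.append(np.ones(idx.size))
        n_obs[c] = idx.size
        n_distinct[c] = len(set(tags[idx]))

    X = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(row_idx), np.concatenate(col_idx))),
        shape=(n, n_cols),
    ).tocsr()
    if n * n_cols <= _DENSE_LIMIT:
        X = X.toarray()
    return DesignMatrix(
        X=X,
        y=y,
        dna_replicates=list(replicates),
        variants=variants,
        row_tags=tags,
        row_replicates=rep_of_row,
        n_obs=n_obs,
        n_distinct_tags=n_distinct,
    )


def _ordered_cholesky(gram: np.ndarray, rel_tol: float = 1e-10):
    """Cholesky that walks columns in order, dropping aliased ones.

    Returns (kept column indices, lower-triangular factor of the kept
    Gram block). Dropping the *later* of two collinear columns follows
    from the in-order walk.
    """
    from scipy.linalg import solve_triangular

    p = gram.shape[0]
    kept: list[int] = []
    dropped: list[int] = []
    L = np.zeros((p, p))
    for j in range(p):
        k = len(kept)
        if k:
            w = solve_triangular(L[:k, :k], gram[kept, j], lower=True)
        else:
            w = np.zeros(0)
        s = gram[j, j] - w @ w
        if s <= rel_tol * max(gram[j, j], 1.0):
            dropped.append(j)
            continue
        L[k, :k] = w
        L[k, k] = np.sqrt(s)
        kept.append(j)
    return kept, dropped, L[: len(kept), : len(kept)]


def fit_effects(design: DesignMatrix, ci_level: float = 0.95) -> tuple[pd.DataFrame, dict]:
    """Ordinary least squares on the design; one estimate per variant.

    Solves the normal equations with an in-column-order Cholesky so that
    aliased (collinear) columns are detected and the later column is
    dropped. Returns the per-variant estimates and fit diagnostics
    (intercept, DNA slopes, aliased columns, RSS, dof).
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise FitError(f"design has {n} rows for {p} columns")
    gram = (X.T @ X).toarray() if sp.issparse(X) else X.T @ X
    xty = np.asarray(X.T @ y).ravel()

    kept, dropped, L = _ordered_cholesky(gram)
    if not kept:
        raise FitError("all columns aliased")
    from scipy.linalg import cho_solve, solve_triangular

    beta_kept = cho_solve((L, True), xty[kept])
    beta = np.zeros(p)
    beta[kept] = beta_kept

    residuals = y - (X @ beta)
    rss = float(residuals @ residuals)
    dof = n - len(kept)
    if dof <= 0:
        raise FitError("no residual degrees of freedom")
    sigma2 = rss / dof
    # diag of inv(gram_kept) via the Cholesky factor
    inv_L = solve_triangular(L, np.eye(len(kept)), lower=True)
    diag_cov = (inv_L**2).sum(axis=0) * sigma2
    se = np.full(p, np.nan)
    se[kept] = np.sqrt(diag_cov)

    tcrit = stats.t.ppf(0.5 + ci_level / 2, dof)
    n_fixed = design.n_fixed
    records = []
    aliased_variants = []
    for c, variant in enumerate(design.variants):
        col = n_fixed + c
        if col in dropped or np.isnan(se[col]):
            aliased_variants.append(variant)
            continue
        tstat = beta[col] / se[col]
        records.append(
            {
                "variant": variant,
                "position": variant.position,
                "ref": variant.ref,
                "alt": variant.alt,
                "log2_effect": beta[col],
                "std_error": se[col],
                "p_value": float(2 * stats.t.sf(abs(tstat), dof)),
                "ci_low": beta[col] - tcrit * se[col],
                "ci_high": beta[col] + tcrit * se[col],
                "n_obs": int(design.n_obs[c]),
                "n_distinct_tags": int(design.n_distinct_tags[c]),
            }
        )
    estimates = pd.DataFrame.from_records(
        records,
        columns=[
            "variant", "position", "ref", "alt", "log2_effect", "std_error",
            "p_value", "ci_low", "ci_high", "n_obs", "n_distinct_tags",
        ],
    )
    diagnostics = {
        "intercept": float(beta[len(design.dna_replicates)]),
        "dna_slopes": {
            int(rep): float(beta[i]) for i, rep in enumerate(design.dna_replicates)
        },
        "aliased_variants": aliased_variants,
        "aliased_fixed_columns": [d for d in dropped if d < n_fixed],
        "rss": rss,
        "dof": dof,
        "sigma2": sigma2,
        "n_rows": n,
        "n_columns": p,
    }
    return estimates, diagnostics


def filter_min_tags(
    estimates: pd.DataFrame, min_tags: int = 10, tag_count_mode: str = "rows"
) -> pd.DataFrame:
    """Drop variants below the tag-support threshold (the fit is not re-run).

    ``tag_count_mode='rows'`` counts (tag, replicate) observations in the
    combined design; ``'distinct_tags'`` counts distinct tag sequences.
    """
    if tag_count_mode == "rows":
        support = estimates["n_obs"]
    elif tag_count_mode == "distinct_tags":
        support = estimates["n_distinct_tags"]
    else:
        raise ValueError(f"unknown tag_count_mode {tag_count_mode!r}")
    return estimates[support >= min_tags].reset_index(drop=True)


def significance_report(
    estimates: pd.DataFrame,
    alpha: float = 1e-5,
    fold_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label each variant activating / repressing / nonsignificant.

    ``fold_threshold`` (e.g. 2.0) additionally requires
    ``|log2_effect| >= log2(fold_threshold)``.
    """
    labelled = estimates.copy()
    significant = labelled["p_value"] < alpha
    if fold_threshold is not None:
        significant &= labelled["log2_effect"].abs() >= np.log2(fold_threshold)
    label = np.where(
        significant & (labelled["log2_effect"] > 0), "activating",
        np.where(significant & (labelled["log2_effect"] < 0), "repressing", "nonsignificant"),
    )
    labelled["label"] = label
    act = labelled[labelled["label"] == "activating"]
    rep = labelled[labelled["label"] == "repressing"]
    summary = {
        "n_variants": len(labelled),
        "n_significant": int(significant.sum()),
        "n_activating": len(act),
        "n_repressing": len(rep),
        "median_abs_effect_activating": float(act["log2_effect"].abs().median())
        if len(act) else float("nan"),
        "median_abs_effect_repressing": float(rep["log2_effect"].abs().median())
        if len(rep) else float("nan"),
    }
    return labelled, summary


def compare_conditions(
    estimates_a: pd.DataFrame, estimates_b: pd.DataFrame
) -> pd.DataFrame:
    """Variants whose confidence intervals do not overlap between conditions.

    Intervals come from the fits (95% by default there); a variant is
    flagged iff [ci_low, ci_high] of A and B are disjoint.
    """
    a = estimates_a.set_index(["position", "ref", "alt"])
    b = estimates_b.set_index(["position", "ref", "alt"])
    shared = a.index.intersection(b.index)
    if shared.empty:
        import warnings

        warnings.warn("no shared variants between conditions")
        return pd.DataFrame(
            columns=["position", "ref", "alt", "effect_a", "effect_b", "different", "direction"]
        )
    a, b = a.loc[shared], b.loc[shared]
    disjoint = (a["ci_high"] < b["ci_low"]) | (b["ci_high"] < a["ci_low"])
    direction = np.where(
        ~disjoint, "same", np.where(b["log2_effect"] > a["log2_effect"], "b_higher", "a_higher")
    )
    out = pd.DataFrame(
        {
            "effect_a": a["log2_effect"],
            "effect_b": b["log2_effect"],
            "ci_low_a": a["ci_low"],
            "ci_high_a": a["ci_high"],
            "ci_low_b": b["ci_low"],
            "ci_high_b": b["ci_high"],
            "different": disjoint,
            "direction": direction,
        }
    ).reset_index()
    return out
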