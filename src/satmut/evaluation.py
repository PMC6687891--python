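"""Benchmarking annotation scores against measured variant effects.

Rank/linear correlations per element, and the matched top-N
classification experiment: positives are the largest significant
effects, negatives are resampled near-zero-effect variants with the
per-element class contribution preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class AnnotationTrack:
    """Scores keyed by position (per_position) or (position, alt)."""

    name: str
    granularity: str  # per_position | per_allele
    scores: dict

    def __post_init__(self) -> None:
        if self.granularity not in ("per_position", "per_allele"):
            raise ValueError(f"unknown granularity {self.granularity!r}")

    def score_for(self, position: int, alt: str | None = None):
        """Per-position tracks give every substitution the same value."""
        if self.granularity == "per_position":
            return self.scores.get(position)
        return self.scores.get((position, alt))

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "AnnotationTrack":
        if "alt" in frame.columns:
            scores = {
                (int(p), a): float(s)
                for p, a, s in zip(frame["position"], frame["alt"], frame["score"])
            }
            return cls(name, "per_allele", scores)
        scores = {int(p): float(s) for p, s in zip(frame["position"], frame["score"])}
        return cls(name, "per_position", scores)


def attach_scores(estimates: pd.DataFrame, track: AnnotationTrack) -> pd.Series:
    return pd.Series(
        [track.score_for(int(p), a) for p, a in zip(estimates["position"], estimates["alt"])],
        index=estimates.index,
        dtype=float,
    )


def correlate_scores(
    estimates: pd.DataFrame,
    track: AnnotationTrack,
    method: str = "spearman",
    use_absolute_effect: bool = True,
    signed: bool = False,
) -> dict:
    """Correlation of effects with a score track over their intersection.

    Absolute effects by default; ``signed=True`` keeps directionality for
    direction-aware scores. Variants without a score are dropped and
    counted. Zero-variance inputs report NA with a reason.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    scores = attach_scores(estimates, track)
    mask = scores.notna()
    effects = estimates.loc[mask, "log2_effect"].to_numpy(dtype=float)
    paired = scores[mask].to_numpy(dtype=float)
    if effects.size < 3:
        raise ValueError(f"only {effects.size} paired values; need >= 3")
    if use_absolute_effect and not signed:
        effects = np.abs(effects)
    if np.ptp(paired) == 0 or np.ptp(effects) == 0:
        return {"correlation": None, "n": int(effects.size),
                "n_missing_score": int((~mask).sum()), "reason": "zero variance"}
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = fn(effects, paired)
    return {"correlation": float(r), "p_value": float(p), "n": int(effects.size),
            "n_missing_score": int((~mask).sum())}


@dataclass
class ClassificationResult:
    score_name: str
    auroc: np.ndarray
    auprc: np.ndarray
    resample_logs: list[dict] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(self.auroc.mean())

    @property
    def mean_auprc(self) -> float:
        return float(self.auprc.mean())


def select_positives(
    estimates: pd.DataFrame, top_n: int, alpha: float = 1e-5
) -> pd.DataFrame:
    """Top-N significant variants by |effect|; boundary ties break by p."""
    significant = estimates[estimates["p_value"] < alpha]
    ranked = significant.assign(_abs=significant["log2_effect"].abs()).sort_values(
        ["_abs", "p_value"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(top_n).drop(columns="_abs")


def classification_eval(
    estimates: pd.DataFrame,
    tracks: list[AnnotationTrack],
    top_n: int = 200,
    null_abs_effect_max: float = 0.05,
    alpha: float = 1e-5,
    n_resamples: int = 100,
    seed: int = 0,
) -> dict[str, ClassificationResult]:
    """Matched top-N classification with resampled near-zero negatives.

    ``estimates`` must carry an ``element`` column. Positives are the
    ``top_n`` largest significant |effects| pooled across elements;
    each resample draws the same number of negatives per element
    (|effect| < ``null_abs_effect_max``) without replacement,
    downsampling positives where negatives are scarce. AUROC/AUPRC are
    computed per resample for every track.
    """
    if "element" not in estimates.columns:
        estimates = estimates.assign(element="all")
    positives = select_positives(estimates, top_n, alpha)
    negative_pool = estimates[estimates["log2_effect"].abs() < null_abs_effect_max]

    pos_by_element = {e: g for e, g in positives.groupby("element")}
    neg_by_element = {e: g for e, g in negative_pool.groupby("element")}
    usable: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for element, pos in pos_by_element.items():
        neg = neg_by_element.get(element)
        if neg is None or neg.empty:
            warnings.warn(f"element {element}: empty negative pool; excluded")
            continue
        usable[element] = (pos, neg)
    if not usable:
        raise ValueError("no element has both positives and negatives")

    score_values = {t.name: attach_scores(estimates, t) for t in tracks}
    master = np.random.default_rng(seed)
    resample_seeds = master.integers(0, 2**32, size=n_resamples)

    results = {
        t.name: ClassificationResult(t.name, np.zeros(n_resamples), np.zeros(n_resamples))
        for t in tracks
    }
    for i, rseed in enumerate(resample_seeds):
        rng = np.random.default_rng(rseed)
        pos_idx: list[np.ndarray] = []
        neg_idx: list[np.ndarray] = []
        log: dict = {}
        for element, (pos, neg) in sorted(usable.items()):
            n_take = min(len(pos), len(neg))
            p_idx = pos.index.to_numpy()
            if n_take < len(pos):  # negatives scarce: downsample positives
                p_idx = rng.choice(p_idx, size=n_take, replace=False)
            n_idx = rng.choice(neg.index.to_numpy(), size=n_take, replace=False)
            pos_idx.append(p_idx)
            neg_idx.append(n_idx)
            log[element] = {"n_pos": int(n_take), "n_neg": int(n_take)}
        idx = np.concatenate(pos_idx + neg_idx)
        labels = np.concatenate(
            [np.ones(sum(len(a) for a in pos_idx)), np.zeros(sum(len(a) for a in neg_idx))]
        )
        for track in tracks:
            values = score_values[track.name].loc[idx].to_numpy(dtype=float)
            ok = ~np.isnan(values)
            if len(np.unique(labels[ok])) < 2:
                results[track.name].auroc[i] = np.nan
                results[track.name].auprc[i] = np.nan
                continue
            results[track.name].auroc[i] = roc_auc_score(labels[ok], values[ok])
            results[track.name].auprc[i] = average_precision_score(labels[ok], values[ok])
        for track in tracks:
            results[track.name].resample_logs.append(log)
    return results
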