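"""Ten-fold cross-validated evaluation of pair scoring.

Known interacting pairs (positives) are shuffled and split into ten
near-equal parts.  Each part in turn is the test fold; an equal number of
non-interacting pairs is drawn uniformly at random (resampling on
collision with a positive or an already-drawn pair) as test negatives, and
the remaining 90% of positives plus a matched negative sample form the
training set.  Similarity views, diffusion and embeddings are computed
once on the full network — they never see the drug-protein edges being
predicted — and only the projection Z is refit per fold with the test
positives masked out of the interaction matrix.

An optional homolog filter removes test pairs that are redundant with the
training set: any pair whose protein has sequence similarity >= 0.4 to a
training-pair protein, or whose drug has similarity >= 0.6 to a
training-pair drug, is dropped before metrics are computed.  Popular,
heavily homologous targets otherwise inflate apparent performance.

Reported metrics per fold: AUROC, AUPRC (threshold-free), and precision,
recall, F1 and MCC at a threshold chosen to maximize F1 on the training
fold (never on the test fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import diffusion, features, similarity

Pair = Tuple[int, int]

METRIC_NAMES = ("precision", "recall", "f1", "mcc", "auroc", "auprc")
THRESHOLD_POLICIES = ("max_f1_train", "fixed")


@dataclass
class CVFold:
    """One fold's pair assignments.  Test positives across the k folds
    partition the full positive set; negative samples are disjoint from
    all positives and matched in count."""

    index: int
    test_positives: List[Pair]
    test_negatives: List[Pair]
    train_positives: List[Pair]
    train_negatives: List[Pair]
    seed: int


def sample_negatives(
    A: np.ndarray,
    count: int,
    *,
    exclude: Iterable[Pair] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> List[Pair]:
    """Uniformly sample *count* distinct non-interacting (drug, protein) pairs.

    A drawn pair that is a known positive, already drawn, or in *exclude*
    is discarded and redrawn until *count* distinct eligible pairs exist.
    """
    A = np.asarray(A)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_d, n_p = A.shape
    positives = {(int(i), int(j)) for i, j in zip(*np.nonzero(A))}
    excluded = set(map(tuple, exclude))
    capacity = n_d * n_p - len(positives | excluded)
    if count > capacity:
        raise ValueError(f"cannot draw {count} negatives; only {capacity} eligible")
    drawn: set = set()
    result: List[Pair] = []
    while len(result) < count:
        i = int(rng.integers(n_d))
        j = int(rng.integers(n_p))
        pair = (i, j)
        if pair in positives or pair in excluded or pair in drawn:
            continue
        drawn.add(pair)
        result.append(pair)
    return result


def make_folds(A: np.ndarray, k: int = 10, seed: int = 0) -> List[CVFold]:
    """Shuffle all positives with *seed* and split into *k* test folds,
    each with a matched negative sample."""
    A = np.asarray(A)
    positives = [(int(i), int(j)) for i, j in zip(*np.nonzero(A))]
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    shuffled = [positives[i] for i in order]
    parts = np.array_split(np.arange(len(shuffled)), k)
    folds: List[CVFold] = []
    for fold_idx, part in enumerate(parts, start=1):
        part_set = set(part.tolist())
        test_pos = [shuffled[i] for i in part]
        train_pos = [p for i, p in enumerate(shuffled) if i not in part_set]
        test_neg = sample_negatives(A, len(test_pos), rng=rng)
        train_neg = sample_negatives(A, len(train_pos), exclude=test_neg, rng=rng)
        folds.append(
            CVFold(
                index=fold_idx,
                test_positives=test_pos,
                test_negatives=test_neg,
                train_positives=train_pos,
                train_negatives=train_neg,
                seed=seed,
            )
        )
    return folds


def homolog_filter(
    pairs: Sequence[Pair],
    protein_similarity: np.ndarray,
    drug_similarity: np.ndarray,
    reference_pairs: Sequence[Pair],
    *,
    protein_threshold: float = 0.4,
    drug_threshold: float = 0.6,
) -> List[Pair]:
    """Drop evaluation pairs redundant with the reference (training) pairs.

    A pair (d, p) is removed when any reference pair (d', p') has
    protein similarity(p, p') >= protein_threshold or drug
    similarity(d, d') >= drug_threshold.
    """
    protein_similarity = np.asarray(protein_similarity)
    drug_similarity = np.asarray(drug_similarity)
    ref_drugs = sorted({d for d, _ in reference_pairs})
    ref_proteins = sorted({p for _, p in reference_pairs})
    if not ref_drugs:
        return list(pairs)
    kept = []
    for d, p in pairs:
        if drug_similarity[d, ref_drugs].max() >= drug_threshold:
            continue
        if protein_similarity[p, ref_proteins].max() >= protein_threshold:
            continue
        kept.append((d, p))
    return kept


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> Tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with prediction = score >= threshold."""
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tp, fp, tn, fn


def _safe_ratio(num: float, denom: float) -> Tuple[float, bool]:
    if denom == 0:
        return 0.0, True
    return num / denom, False


def best_f1_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score threshold maximizing F1 on (scores, labels)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    candidates = np.unique(scores)
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        tp, fp, tn, fn = confusion_counts(scores, labels, t)
        prec, _ = _safe_ratio(tp, tp + fp)
        rec, _ = _safe_ratio(tp, tp + fn)
        f1, _ = _safe_ratio(2 * prec * rec, prec + rec)
        if f1 > best_f1:
            best_f1, best_t = f1, t
    return float(best_t)


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    *,
    threshold: float | None = None,
) -> Dict[str, float]:
    """All six metrics for one fold.

    AUROC is the tie-aware rank statistic (trapezoidal ROC area); AUPRC is
    the step-interpolated precision-recall area.  Binary metrics use
    *threshold* (default: the F1-maximizing threshold on these scores —
    callers doing honest evaluation pass a threshold fit on training
    data).  Degenerate ratios (zero denominator) are reported as 0 and
    flagged in ``zero_division``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPRC need both classes present")
    if threshold is None:
        threshold = best_f1_threshold(scores, labels)
    tp, fp, tn, fn = confusion_counts(scores, labels, threshold)
    precision, flag_p = _safe_ratio(tp, tp + fp)
    recall, flag_r = _safe_ratio(tp, tp + fn)
    f1, flag_f = _safe_ratio(2 * precision * recall, precision + recall)
    mcc_denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc, flag_m = _safe_ratio(float(tp) * tn - float(fp) * fn, mcc_denom)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "threshold": float(threshold),
        "zero_division": bool(flag_p or flag_r or flag_f or flag_m),
    }


def aggregate_metrics(per_fold: List[Dict[str, float]]) -> Dict[str, Dict[str, float]]:
    """Mean and standard deviation of each metric across folds."""
    out: Dict[str, Dict[str, float]] = {"mean": {}, "sd": {}}
    for name in METRIC_NAMES:
        values = np.array([m[name] for m in per_fold])
        out["mean"][name] = float(values.mean())
        out["sd"][name] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# full cross-validated pipeline


@dataclass
class PipelineConfig:
    """End-to-end settings: diffusion variant and walk parameters,
    embedding sizes, ridge penalty, CV layout and homolog filtering."""

    variant: str = "ISLRWR"
    c: float = 0.85
    isolated_policy: str = "teleport"
    f_d: int = 100
    f_p: int = 100
    smoothing: float | None = None
    lam: float = 0.1
    folds: int = 10
    seed: int = 0
    threshold_policy: str = "max_f1_train"
    homolog_filter: bool = False
    protein_threshold: float = 0.4
    drug_threshold: float = 0.6
    solver: str = "closed_form"

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_CHOICES:
            raise ValueError(f"variant must be one of {VARIANT_CHOICES}")
        if self.threshold_policy not in THRESHOLD_POLICIES:
            raise ValueError(f"threshold_policy must be one of {THRESHOLD_POLICIES}")


VARIANT_CHOICES = ("RWR", "MHRW", "IMRWR", "ISLRWR", "ISLHRWR")


def compute_embeddings(
    net,
    cfg: PipelineConfig,
    *,
    drug_structure: np.ndarray | None = None,
    protein_genome: np.ndarray | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Similarity views -> diffusion states -> (X, Y) feature blocks.

    The ISLHRWR variant recomputes all profile-derived similarity views
    with Hamming similarity and then diffuses with the ISLRWR transition;
    structure/genome views are unchanged.
    """
    profile_metric = "hamming" if cfg.variant == "ISLHRWR" else "jaccard"
    walk_variant = "ISLRWR" if cfg.variant == "ISLHRWR" else cfg.variant
    drug_views, protein_views = similarity.build_similarity_views(
        net,
        drug_structure=drug_structure,
        protein_genome=protein_genome,
        profile_metric=profile_metric,
    )
    dcfg = diffusion.DiffusionConfig(c=cfg.c, isolated_policy=cfg.isolated_policy)
    drug_states = diffusion.diffuse_all(
        drug_views, walk_variant, dcfg, method=cfg.solver
    )
    protein_states = diffusion.diffuse_all(
        protein_views, walk_variant, dcfg, method=cfg.solver
    )
    X = features.embed_multinetwork(drug_states, cfg.f_d,
                                    smoothing=cfg.smoothing, seed=cfg.seed)
    Y = features.embed_multinetwork(protein_states, cfg.f_p,
                                    smoothing=cfg.smoothing, seed=cfg.seed)
    return X, Y


def _fold_threshold(
    scores_matrix: np.ndarray, fold: CVFold, cfg: PipelineConfig
) -> float:
    train_pairs = fold.train_positives + fold.train_negatives
    train_scores = np.array([scores_matrix[d, p] for d, p in train_pairs])
    train_labels = np.array(
        [1] * len(fold.train_positives) + [0] * len(fold.train_negatives)
    )
    if cfg.threshold_policy == "max_f1_train":
        return best_f1_threshold(train_scores, train_labels)
    # fixed policy: midpoint of the min-max scaled training scores
    return float((train_scores.min() + train_scores.max()) / 2.0)


def run_cv(
    net,
    cfg: PipelineConfig,
    *,
    drug_structure: np.ndarray | None = None,
    protein_genome: np.ndarray | None = None,
    protein_similarity_for_filter: np.ndarray | None = None,
    drug_similarity_for_filter: np.ndarray | None = None,
) -> Dict:
    """Ten-fold cross-validation of one diffusion variant on one network.

    Embeddings are computed once on the full network; per fold the test
    positives are masked from the interaction matrix, Z is refit, test
    pairs are scored, and metrics are computed at a training-fold
    threshold.  Returns per-fold metrics plus mean +/- sd aggregates and
    the full configuration.
    """
    A = np.asarray(net.interactions)
    X, Y = compute_embeddings(
        net, cfg, drug_structure=drug_structure, protein_genome=protein_genome
    )
    folds = make_folds(A, k=cfg.folds, seed=cfg.seed)
    if cfg.homolog_filter:
        if protein_similarity_for_filter is None:
            protein_similarity_for_filter = (
                protein_genome
                if protein_genome is not None
                else similarity.profile_similarity_matrix(
                    net.relations["protein_protein"]
                )
            )
        if drug_similarity_for_filter is None:
            drug_similarity_for_filter = (
                drug_structure
                if drug_structure is not None
                else similarity.profile_similarity_matrix(net.relations["drug_drug"])
            )
    per_fold: List[Dict[str, float]] = []
    fold_details = []
    for fold in folds:
        A_train = A.astype(float).copy()
        for d, p in fold.test_positives:
            A_train[d, p] = 0.0
        Z = features.solve_projection(X, Y, A_train, lam=cfg.lam)
        S = features.score_pairs(X, Z, Y)
        threshold = _fold_threshold(S, fold, cfg)
        test_pos, test_neg = fold.test_positives, fold.test_negatives
        n_before = len(test_pos) + len(test_neg)
        if cfg.homolog_filter:
            ref = fold.train_positives
            test_pos = homolog_filter(
                test_pos, protein_similarity_for_filter,
                drug_similarity_for_filter, ref,
                protein_threshold=cfg.protein_threshold,
                drug_threshold=cfg.drug_threshold,
            )
            test_neg = homolog_filter(
                test_neg, protein_similarity_for_filter,
                drug_similarity_for_filter, ref,
                protein_threshold=cfg.protein_threshold,
                drug_threshold=cfg.drug_threshold,
            )
        pairs = list(test_pos) + list(test_neg)
        labels = [1] * len(test_pos) + [0] * len(test_neg)
        scores = [S[d, p] for d, p in pairs]
        metrics = compute_metrics(scores, labels, threshold=threshold)
        metrics["fold"] = fold.index
        metrics["n_test"] = len(pairs)
        metrics["n_filtered"] = n_before - len(pairs)
        per_fold.append(metrics)
        fold_details.append(fold)
    report = aggregate_metrics(per_fold)
    report["per_fold"] = per_fold
    report["config"] = {
        "variant": cfg.variant,
        "c": cfg.c,
        "isolated_policy": cfg.isolated_policy,
        "f_d": cfg.f_d,
        "f_p": cfg.f_p,
        "lam": cfg.lam,
        "folds": cfg.folds,
        "seed": cfg.seed,
        "threshold_policy": cfg.threshold_policy,
        "homolog_filter": cfg.homolog_filter,
        "embeddings_refit_per_fold": False,
    }
    return report
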