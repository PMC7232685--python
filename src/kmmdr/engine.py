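"""Exhaustive q-way interaction search with 10-fold cross-validation.

For every size-q subset of SNPs, each cross-validation fold trains a
high/low-risk cell classification on its 9/10 training split and scores the
pooled H vs L groups.  The fold's winner (maximum training score) feeds the
cross-validation consistency count (CVC); a single pooled testing score per
subset is computed on the union of all held-out folds, each labelled by its
own training-fold rule.  Best-model selection and permutation p-values sit
on top.

Scores are method-dependent: the KM-median and Surv-MDR classifiers use the
squared log-rank statistic Z² of the H vs L split, while the residual-based
comparators (Cox-MDR, AFT-MDR) use balanced accuracy of the cell label
against the subject's score sign, as in the generalized-MDR family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, classifiers
from .classifiers import CellClassification, GenotypeMatrix
from .errors import InvalidInputError, MethodNotApplicableError, NoModelError
from .survival_core import SurvivalSample, is_estimable

__all__ = [
    "METHODS",
    "FoldAssignment",
    "ModelResult",
    "SearchReport",
    "make_folds",
    "run_cv",
    "select_best",
    "permutation_test",
]

logger = logging.getLogger(__name__)

METHODS = ("km", "surv", "cox", "aft")
SELECTION_ORDERS = ("test_score_first", "cvc_first")


@dataclass(frozen=True)
class FoldAssignment:
    """k-fold partition stratified by event status."""

    fold_id: np.ndarray  # per subject, in 1..k
    k: int
    seed: int


@dataclass
class ModelResult:
    """One SNP combination's cross-validation summary.

    ``training_score`` is the mean of the per-fold training scores and
    ``testing_score`` the single pooled-testing statistic; both are squared
    log-rank statistics for the km/surv methods and balanced accuracies for
    cox/aft.
    """

    snps: tuple[str, ...]
    training_score: float
    testing_score: float
    cvc: int
    p_value: float | None = None
    per_fold: list = field(default_factory=list, repr=False)
    failed_folds: int = 0
    skipped: bool = False


@dataclass
class SearchReport:
    """All candidate models of one interaction order, ranked best-first."""

    q: int
    method: str
    results: list[ModelResult]
    settings: dict = field(default_factory=dict)

    @property
    def best(self) -> ModelResult:
        if not self.results or self.results[0].skipped:
            raise NoModelError(f"no usable q={self.q} model")
        return self.results[0]


def make_folds(sample: SurvivalSample, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random k-fold partition, stratified so each fold keeps the overall
    censoring fraction (fold sizes within each status stratum differ by at
    most one).  Deterministic for a fixed seed."""
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    if sample.n < k:
        raise InvalidInputError(f"need at least k={k} subjects, got {sample.n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(sample.n, dtype=np.int64)
    offset = 0
    for value in (1, 0):
        idx = np.flatnonzero(sample.status == value)
        if idx.size == 0:
            continue
        rng.shuffle(idx)
        fold[idx] = (np.arange(idx.size) + offset) % k + 1
        offset = (offset + idx.size) % k
    return FoldAssignment(fold_id=fold, k=k, seed=seed)


def _balanced_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean recall over the classes present in ``truth``.

    ½(sensitivity + specificity) when both classes occur; the recall of the
    single present class otherwise.
    """
    recalls = []
    for cls in (True, False):
        m = truth == cls
        if m.any():
            recalls.append(float(np.mean(pred[m] == cls)))
    return float(np.mean(recalls))


def _rank_key(order: str):
    if order == "cvc_first":
        return lambda r: (-r.cvc, -r.testing_score, r.snps)
    return lambda r: (-r.testing_score, -r.cvc, r.snps)


def run_cv(
    sample: SurvivalSample,
    genotypes: GenotypeMatrix,
    q: int,
    method: str,
    folds: FoldAssignment | list[FoldAssignment],
    selection_order: str = "test_score_first",
    keep_classifications: bool = True,
) -> SearchReport:
    """Cross-validated exhaustive search over all C(p, q) SNP subsets.

    Per fold, every subset is trained and scored on the training split; the
    fold winner accrues CVC.  Score ties — which occur with positive
    probability when sparse genotypes yield identical or degenerate H/L
    labelings — are broken in a random order seeded by the fold
    assignment, so reruns are reproducible but no SNP tuple is
    systematically favoured.  Each subset's testing score is computed once on
    the union of held-out folds labelled by their training rules.  A fold
    where the method is not applicable (e.g. the overall KM median is not
    estimable) is marked failed; a subset is reported as skipped when more
    than half its folds fail.

    Passing a list of fold assignments repeats the cross-validation:
    testing and training scores are averaged and CVCs summed across
    repeats.
    """
    if method not in METHODS:
        raise InvalidInputError(f"unknown method {method!r}; expected one of {METHODS}")
    if selection_order not in SELECTION_ORDERS:
        raise InvalidInputError(f"unknown selection_order {selection_order!r}")
    if isinstance(folds, FoldAssignment):
        fold_list = [folds]
    else:
        fold_list = list(folds)
        if not fold_list:
            raise InvalidInputError("at least one fold assignment is required")
    p = genotypes.p
    if not (1 <= q <= p):
        raise InvalidInputError(f"q must satisfy 1 <= q <= p={p}")
    if genotypes.n != sample.n:
        raise InvalidInputError("genotypes and survival sample must align")

    reports = [
        _run_cv_single(sample, genotypes, q, method, fa, selection_order,
                       keep_classifications)
        for fa in fold_list
    ]
    if len(reports) == 1:
        return reports[0]

    # merge repeats: same combo ordering in every repeat
    merged = []
    by_snps = [{r.snps: r for r in rep.results} for rep in reports]
    for r0 in reports[0].results:
        rs = [d[r0.snps] for d in by_snps]
        merged.append(
            ModelResult(
                snps=r0.snps,
                training_score=float(np.mean([r.training_score for r in rs])),
                testing_score=float(np.mean([r.testing_score for r in rs])),
                cvc=int(sum(r.cvc for r in rs)),
                per_fold=[pf for r in rs for pf in r.per_fold],
                failed_folds=sum(r.failed_folds for r in rs),
                skipped=any(r.skipped for r in rs),
            )
        )
    merged.sort(key=_rank_key(selection_order))
    settings = dict(reports[0].settings, cv_repeats=len(reports))
    return SearchReport(q=q, method=method, results=merged, settings=settings)


def _run_cv_single(
    sample: SurvivalSample,
    genotypes: GenotypeMatrix,
    q: int,
    method: str,
    folds: FoldAssignment,
    selection_order: str,
    keep_classifications: bool,
) -> SearchReport:
    n, p, k = sample.n, genotypes.p, folds.k
    order = _kernels.sort_order(sample.time, sample.status)
    t_all = sample.time[order]
    s_all = sample.status[order]
    g_all = genotypes.values[order]
    fold_sorted = folds.fold_id[order]

    combos = list(itertools.combinations(range(p), q))
    n_combos = len(combos)
    n_cells = 3 ** q
    cell_idx = np.empty((n_combos, n), dtype=np.int64)
    for ci, combo in enumerate(combos):
        cell_idx[ci] = classifiers.cell_index(g_all[:, combo])

    if method in ("cox", "aft"):
        fn = classifiers.cox_null_scores if method == "cox" else classifiers.aft_null_scores
        scores_sorted = fn(sample)[order]
        y_sorted = scores_sorted > 0
    else:
        scores_sorted = y_sorted = None

    # ties in training or testing scores (identical or degenerate H/L
    # labelings — common with sparse genotypes) are broken in a random
    # order drawn from the fold seed: deterministic for a rerun, but not
    # systematically favouring any SNP tuple, so null selection stays
    # uniform over exchangeable SNPs
    tie_rank = np.random.default_rng(folds.seed).permutation(n_combos)

    training = np.zeros((n_combos, k))
    fold_failed = np.zeros(k, dtype=bool)
    test_hi = np.zeros((n_combos, n), dtype=bool)
    stored: dict[tuple[int, int], CellClassification] = {}

    for fi in range(k):
        f = fi + 1
        tr = fold_sorted != f
        te = ~tr
        t_tr, s_tr = t_all[tr], s_all[tr]
        overall_med = None
        if method == "km":
            overall_med = _kernels.km_median_sorted(t_tr, s_tr)
            if not is_estimable(overall_med):
                fold_failed[fi] = True
                logger.info("fold %d failed: overall KM median not estimable", f)
                continue
        elif method == "surv" and s_tr.sum() == 0:
            fold_failed[fi] = True
            logger.info("fold %d failed: no events in training split", f)
            continue
        y_tr = y_sorted[tr] if y_sorted is not None else None
        for ci in range(n_combos):
            cidx = cell_idx[ci]
            cidx_tr = cidx[tr]
            if method == "km":
                hi, prov, _ = classifiers.km_cell_labels(
                    cidx_tr, t_tr, s_tr, n_cells, overall_median=overall_med
                )
            elif method == "surv":
                hi, prov = classifiers.surv_cell_labels(cidx_tr, t_tr, s_tr, n_cells)
            else:
                hi, prov = classifiers.score_cell_labels(
                    cidx_tr, scores_sorted[tr], n_cells
                )
            if method in ("km", "surv"):
                training[ci, fi] = _kernels.logrank_score_sorted(t_tr, s_tr, hi[cidx_tr])
            else:
                training[ci, fi] = _balanced_accuracy(y_tr, hi[cidx_tr])
            test_hi[ci, te] = hi[cidx[te]]
            if keep_classifications:
                stored[(ci, fi)] = classifiers._classification_from_arrays(
                    q, hi, prov,
                    overall_med if overall_med is not None else np.nan,
                )

    ok = ~fold_failed
    n_ok = int(ok.sum())
    cvc = np.zeros(n_combos, dtype=np.int64)
    for fi in range(k):
        if fold_failed[fi]:
            continue
        col = training[:, fi]
        tied = np.flatnonzero(col == col.max())
        cvc[tied[np.argmin(tie_rank[tied])]] += 1

    valid_subjects = ok[fold_sorted - 1]
    t_v, s_v = t_all[valid_subjects], s_all[valid_subjects]
    y_v = y_sorted[valid_subjects] if y_sorted is not None else None

    snp_ids = genotypes.snp_ids
    results = []
    result_tie = []
    skip_all = n_ok < (k - n_ok) or n_ok == 0  # more than half the folds failed
    for ci, combo in enumerate(combos):
        if skip_all:
            results.append(
                ModelResult(
                    snps=tuple(snp_ids[i] for i in combo),
                    training_score=0.0, testing_score=0.0, cvc=0,
                    failed_folds=k - n_ok, skipped=True,
                )
            )
            result_tie.append(tie_rank[ci])
            continue
        if method in ("km", "surv"):
            tssc = _kernels.logrank_score_sorted(t_v, s_v, test_hi[ci, valid_subjects])
        else:
            tssc = _balanced_accuracy(y_v, test_hi[ci, valid_subjects])
        per_fold = [
            (fi + 1, float(training[ci, fi]), stored.get((ci, fi)))
            for fi in range(k)
        ]
        results.append(
            ModelResult(
                snps=tuple(snp_ids[i] for i in combo),
                training_score=float(training[ci, ok].mean()),
                testing_score=float(tssc),
                cvc=int(cvc[ci]),
                per_fold=per_fold,
                failed_folds=k - n_ok,
            )
        )
        result_tie.append(tie_rank[ci])
    if skip_all:
        logger.warning(
            "all %d combinations skipped: %d of %d folds failed",
            n_combos, k - n_ok, k,
        )
    if selection_order == "cvc_first":
        key = lambda i: (-results[i].cvc, -results[i].testing_score, result_tie[i])
    else:
        key = lambda i: (-results[i].testing_score, -results[i].cvc, result_tie[i])
    results = [results[i] for i in sorted(range(n_combos), key=key)]
    return SearchReport(
        q=q,
        method=method,
        results=results,
        settings={
            "k": k,
            "fold_seed": folds.seed,
            "selection_order": selection_order,
            "p": p,
        },
    )


def select_best(
    reports: list[SearchReport], selection_order: str = "test_score_first"
) -> ModelResult:
    """Overall best model across interaction orders.

    Default ordering: maximum testing score, then maximum CVC, then the more
    parsimonious (smaller q) model, then the lexicographically smallest SNP
    tuple.  ``selection_order='cvc_first'`` swaps the first two criteria.
    """
    candidates = []
    for rep in reports:
        for r in rep.results:
            if not r.skipped:
                candidates.append((rep.q, r))
                break  # results are ranked; only the top non-skipped competes
    if not candidates:
        raise NoModelError("every candidate model was skipped or failed")
    if selection_order == "cvc_first":
        key = lambda t: (-t[1].cvc, -t[1].testing_score, t[0], t[1].snps)
    else:
        key = lambda t: (-t[1].testing_score, -t[1].cvc, t[0], t[1].snps)
    return min(candidates, key=key)[1]


def permutation_test(
    sample: SurvivalSample,
    genotypes: GenotypeMatrix,
    q: int,
    method: str,
    B: int = 1000,
    seed: int = 0,
    folds: FoldAssignment | None = None,
    selection_order: str = "test_score_first",
) -> dict[tuple[str, ...], float]:
    """Permutation p-value per candidate model.

    The (time, status[, covariate]) rows are permuted jointly against the
    genotype rows B times; each permutation reruns the full cross-validated
    search and contributes its maximum testing score over all combinations
    (a family-wise calibrated null).  For each candidate model,
    p = (1 + #{null max ≥ observed score}) / (1 + B).
    """
    if B < 1:
        raise InvalidInputError("B must be at least 1")
    if folds is None:
        folds = make_folds(sample, seed=seed)
    observed = run_cv(
        sample, genotypes, q, method, folds,
        selection_order=selection_order, keep_classifications=False,
    )
    rng = np.random.default_rng(seed)
    null_max = np.empty(B)
    for b in range(B):
        # permuting the genotype rows realizes the same joint permutation of
        # (time, status) against genotypes while keeping the status-stratified
        # folds aligned with the survival data
        perm = rng.permutation(sample.n)
        g_perm = GenotypeMatrix(
            genotypes.values[perm], genotypes.snp_ids, genotypes.subject_ids
        )
        rep = run_cv(
            sample, g_perm, q, method, folds,
            selection_order=selection_order, keep_classifications=False,
        )
        usable = [r.testing_score for r in rep.results if not r.skipped]
        null_max[b] = max(usable) if usable else 0.0
    return {
        r.snps: float((1 + np.sum(null_max >= r.testing_score)) / (1 + B))
        for r in observed.results
        if not r.skipped
    }
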