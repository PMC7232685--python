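"""High/low-risk reduction of multilocus genotypes.

Four classifiers collapse the 3^q joint-genotype cells of q biallelic SNPs
into a binary risk attribute:

* **KM-MDR** — a cell is high-risk when its Kaplan-Meier median survival
  time is smaller than the overall training median; cells whose own median
  is not estimable fall back to the complement-sample rule.
* **Surv-MDR** — a cell is high-risk when the log-rank statistic comparing
  cell members against everyone else is positive.
* **Cox-MDR** — a cell is high-risk when the sum of its subjects'
  martingale residuals from the genotype-free null Cox model is positive.
* **AFT-MDR** — like Cox-MDR, with negated standardized residuals from a
  null log-normal accelerated-failure-time model.

Cell provenance records which rule labelled each cell, so downstream code
can distinguish a directly-estimated median from the complement fallback or
the empty-cell default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import FitFailureError, InvalidInputError, MethodNotApplicableError
from .survival_core import NOT_ESTIMABLE, SurvivalSample, is_estimable

__all__ = [
    "HIGH",
    "LOW",
    "GenotypeMatrix",
    "CellClassification",
    "classify_km",
    "classify_surv",
    "cox_null_scores",
    "aft_null_scores",
    "classify_scores",
    "assign_groups",
]

HIGH = "HIGH"
LOW = "LOW"

# provenance tags
CELL_MEDIAN = "cell_median"
COMPLEMENT_RULE = "COMPLEMENT_RULE"
EMPTY_DEFAULT = "EMPTY_DEFAULT"
SCORE_SUM = "score_sum"
DEGENERATE_DEFAULT = "degenerate_default"


@dataclass(frozen=True)
class GenotypeMatrix:
    """n subjects × p SNPs, coded as minor-allele counts 0/1/2."""

    values: np.ndarray
    snp_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InvalidInputError("genotype matrix must be 2-dimensional")
        if not np.isin(values, (0, 1, 2)).all():
            raise InvalidInputError("genotype entries must be 0, 1 or 2")
        object.__setattr__(self, "values", values.astype(np.int8))
        snp_ids = tuple(str(s) for s in self.snp_ids)
        subject_ids = tuple(str(s) for s in self.subject_ids)
        if len(snp_ids) != values.shape[1]:
            raise InvalidInputError("snp_ids must match the number of columns")
        if len(subject_ids) != values.shape[0]:
            raise InvalidInputError("subject_ids must match the number of rows")
        if len(set(snp_ids)) != len(snp_ids):
            raise InvalidInputError("snp_ids must be unique")
        if len(set(subject_ids)) != len(subject_ids):
            raise InvalidInputError("subject_ids must be unique")
        object.__setattr__(self, "snp_ids", snp_ids)
        object.__setattr__(self, "subject_ids", subject_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def restrict(self, snps) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given SNP indices or ids."""
        idx = [self.snp_ids.index(s) if isinstance(s, str) else int(s) for s in snps]
        return GenotypeMatrix(
            self.values[:, idx],
            tuple(self.snp_ids[i] for i in idx),
            self.subject_ids,
        )


def cell_index(genotypes: np.ndarray) -> np.ndarray:
    """Base-3 cell index per subject for an (n, q) genotype block.

    The first SNP is the most significant digit, so for q = 2 the cell of
    genotype (i, j) is 3 i + j, matching the (row, column) layout of a
    penetrance table.
    """
    g = np.asarray(genotypes)
    q = g.shape[1]
    idx = np.zeros(g.shape[0], dtype=np.int64)
    for k in range(q):
        idx = idx * 3 + g[:, k]
    return idx


def cell_key(index: int, q: int) -> tuple[int, ...]:
    """Inverse of :func:`cell_index` for a single cell."""
    digits = []
    for _ in range(q):
        digits.append(index % 3)
        index //= 3
    return tuple(reversed(digits))


@dataclass(frozen=True)
class CellClassification:
    """High/low label per multilocus genotype cell, with provenance."""

    q: int
    cells: dict          # q-tuple genotype -> HIGH | LOW
    provenance: dict     # q-tuple genotype -> labelling rule
    overall_median: float = NOT_ESTIMABLE

    def label(self, key: tuple[int, ...]) -> str:
        return self.cells.get(key, LOW)

    @property
    def high_cells(self) -> set:
        return {k for k, v in self.cells.items() if v == HIGH}

    def as_array(self) -> np.ndarray:
        """Boolean HIGH indicator over all 3^q cells (unseen cells LOW)."""
        out = np.zeros(3 ** self.q, dtype=bool)
        for key, lab in self.cells.items():
            if lab == HIGH:
                idx = 0
                for d in key:
                    idx = idx * 3 + d
                out[idx] = True
        return out


def _classification_from_arrays(
    q: int, hi: np.ndarray, prov: list[str | None], overall_median: float
) -> CellClassification:
    cells = {}
    provenance = {}
    for j in range(3 ** q):
        if prov[j] is None:
            continue
        key = cell_key(j, q)
        cells[key] = HIGH if hi[j] else LOW
        provenance[key] = prov[j]
    return CellClassification(q=q, cells=cells, provenance=provenance,
                              overall_median=overall_median)


# ---------------------------------------------------------------------------
# fast array-level classifiers (used directly by the search engine)
# ---------------------------------------------------------------------------

def km_cell_labels(
    cell_idx: np.ndarray,
    time_sorted: np.ndarray,
    status_sorted: np.ndarray,
    n_cells: int,
    overall_median: float | None = None,
):
    """KM-median high-risk indicator per cell on a pre-sorted training sample.

    Returns (hi, provenance, overall_median).  ``cell_idx`` must be aligned
    with the sorted time/status arrays.
    """
    if overall_median is None:
        overall_median = _kernels.km_median_sorted(time_sorted, status_sorted)
    if not is_estimable(overall_median):
        raise MethodNotApplicableError(
            "overall KM median not estimable; the KM-median classifier cannot run"
        )
    hi = np.zeros(n_cells, dtype=bool)
    prov: list[str | None] = [None] * n_cells
    for j in np.unique(cell_idx):
        in_cell = cell_idx == j
        med = _kernels.km_median_sorted(time_sorted[in_cell], status_sorted[in_cell])
        if is_estimable(med):
            hi[j] = med < overall_median
            prov[j] = CELL_MEDIAN
        else:
            comp = ~in_cell
            if comp.any():
                cmed = _kernels.km_median_sorted(time_sorted[comp], status_sorted[comp])
                hi[j] = is_estimable(cmed) and cmed > overall_median
            prov[j] = COMPLEMENT_RULE
    for j in range(n_cells):
        if prov[j] is None:
            prov[j] = EMPTY_DEFAULT
    return hi, prov, overall_median


def surv_cell_labels(
    cell_idx: np.ndarray,
    time_sorted: np.ndarray,
    status_sorted: np.ndarray,
    n_cells: int,
):
    """Per-cell log-rank-sign high-risk indicator (Surv-MDR rule)."""
    hi = np.zeros(n_cells, dtype=bool)
    prov: list[str | None] = [None] * n_cells
    for j in np.unique(cell_idx):
        in_cell = cell_idx == j
        z, _, _ = _kernels.logrank_sorted(time_sorted, status_sorted, in_cell)
        if np.isnan(z):
            prov[j] = DEGENERATE_DEFAULT
        else:
            hi[j] = z > 0
            prov[j] = SCORE_SUM
    for j in range(n_cells):
        if prov[j] is None:
            prov[j] = EMPTY_DEFAULT
    return hi, prov


def score_cell_labels(cell_idx: np.ndarray, scores: np.ndarray, n_cells: int):
    """High-risk indicator per cell from per-subject score sums (> 0 rule)."""
    sums = np.bincount(cell_idx, weights=scores, minlength=n_cells)
    counts = np.bincount(cell_idx, minlength=n_cells)
    hi = sums > 0
    prov: list[str | None] = [
        SCORE_SUM if counts[j] > 0 else EMPTY_DEFAULT for j in range(n_cells)
    ]
    hi[counts == 0] = False
    return hi, prov


# ---------------------------------------------------------------------------
# public classifier interface
# ---------------------------------------------------------------------------

def _prepare(genotypes: GenotypeMatrix, train: SurvivalSample):
    if genotypes.n != train.n:
        raise InvalidInputError("genotypes and survival sample must align")
    order, t, s = train.sorted_arrays()
    cidx = cell_index(genotypes.values)[order]
    return cidx, t, s, genotypes.p


def classify_km(genotypes: GenotypeMatrix, train: SurvivalSample) -> CellClassification:
    """KM-MDR: cell j is HIGH iff its KM median t_mj < the overall median t_m.

    Ties (t_mj = t_m) are LOW.  A cell whose median is not estimable is
    labelled by the complement rule: HIGH iff the KM median of all training
    subjects outside the cell is estimable and exceeds t_m.  Empty cells
    default to LOW.

    Raises :class:`MethodNotApplicableError` when t_m itself is not
    estimable.
    """
    cidx, t, s, q = _prepare(genotypes, train)
    hi, prov, med = km_cell_labels(cidx, t, s, 3 ** q)
    return _classification_from_arrays(q, hi, prov, med)


def classify_surv(genotypes: GenotypeMatrix, train: SurvivalSample) -> CellClassification:
    """Surv-MDR: cell j is HIGH iff log-rank Z (cell vs rest) is positive."""
    if train.n_events == 0:
        raise MethodNotApplicableError("Surv-MDR requires at least one event")
    cidx, t, s, q = _prepare(genotypes, train)
    hi, prov = surv_cell_labels(cidx, t, s, 3 ** q)
    med = _kernels.km_median_sorted(t, s)
    return _classification_from_arrays(q, hi, prov, med)


def cox_null_scores(train: SurvivalSample) -> np.ndarray:
    """Martingale residuals under the genotype-free null Cox model.

    score_i = status_i − Λ̂(time_i)·exp(z_i·γ̂).  With covariates, γ̂ and the
    Breslow baseline come from a Cox fit on the covariates alone; with no
    covariates the null model degenerates to the Nelson-Aalen cumulative
    hazard.  Positive residuals flag earlier-than-expected events.
    """
    if train.covariates is None:
        order, t, s = train.sorted_arrays()
        cumhaz = _kernels.nelson_aalen_at_times_sorted(t, s)
        scores = np.empty(train.n)
        scores[order] = s - cumhaz
        return scores

    import pandas as pd
    from lifelines import CoxPHFitter

    cov = train.covariates
    df = pd.DataFrame(cov, columns=[f"z{i}" for i in range(cov.shape[1])])
    df["time"] = train.time
    df["status"] = train.status.astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="status")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        raise FitFailureError("null Cox model failed to converge", exc) from exc
    resid = cph.compute_residuals(df, kind="martingale")["martingale"]
    return resid.reindex(df.index).to_numpy()


def aft_null_scores(train: SurvivalSample) -> np.ndarray:
    """Negated standardized residuals under a null log-normal AFT model.

    score_i = −(log(time_i) − μ̂ − z_i·γ̂)/σ̂, so larger scores mean shorter
    survival than the null model predicts (higher risk).  Censored subjects
    enter with their censored time.  The null fit is by maximum likelihood
    with right censoring.
    """
    import pandas as pd

    if np.any(train.time <= 0):
        raise InvalidInputError("AFT residuals require strictly positive times")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if train.covariates is None:
                from lifelines import LogNormalFitter

                lnf = LogNormalFitter()
                lnf.fit(train.time, train.status)
                mu, sigma = float(lnf.mu_), float(lnf.sigma_)
                linpred = np.full(train.n, mu)
            else:
                from lifelines import LogNormalAFTFitter

                cov = train.covariates
                df = pd.DataFrame(cov, columns=[f"z{i}" for i in range(cov.shape[1])])
                df["time"] = train.time
                df["status"] = train.status.astype(int)
                aft = LogNormalAFTFitter()
                aft.fit(df, duration_col="time", event_col="status")
                mu = float(aft.params_[("mu_", "Intercept")])
                gamma = np.array(
                    [aft.params_[("mu_", f"z{i}")] for i in range(cov.shape[1])]
                )
                sigma = float(np.exp(aft.params_[("sigma_", "Intercept")]))
                linpred = mu + cov @ gamma
    except FitFailureError:
        raise
    except Exception as exc:
        raise FitFailureError("null AFT model failed to converge", exc) from exc
    return -(np.log(train.time) - linpred) / sigma


def classify_scores(genotypes: GenotypeMatrix, scores: np.ndarray) -> CellClassification:
    """Score-sum rule shared by Cox-MDR and AFT-MDR.

    Cell j is HIGH iff the sum of its subjects' scores is strictly positive;
    empty cells and exact-zero sums are LOW.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != genotypes.n:
        raise InvalidInputError("scores must align with genotype rows")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("subject scores must be finite")
    q = genotypes.p
    cidx = cell_index(genotypes.values)
    hi, prov = score_cell_labels(cidx, scores, 3 ** q)
    return _classification_from_arrays(q, hi, prov, NOT_ESTIMABLE)


def assign_groups(
    classification: CellClassification, genotypes: GenotypeMatrix
) -> np.ndarray:
    """Pool cells: per-subject boolean high-risk label from its cell's label.

    Cells absent from the training classification (possible for testing
    folds) default to LOW with a warning.
    """
    if genotypes.p != classification.q:
        raise InvalidInputError("genotype matrix order must equal the classification q")
    hi = classification.as_array()
    cidx = cell_index(genotypes.values)
    seen = {k for k in classification.cells}
    unseen = {cell_key(int(j), classification.q) for j in np.unique(cidx)} - seen
    if unseen:
        warnings.warn(
            f"{len(unseen)} genotype cell(s) unseen in training defaulted to LOW: "
            f"{sorted(unseen)}",
            stacklevel=2,
        )
    return hi[cidx]
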