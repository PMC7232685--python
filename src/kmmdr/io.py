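"""Readers and writers for genotype/phenotype tables and run configs.

Delimited files are TSV or CSV, autodetected from the extension (``.csv``
uses commas, anything else tabs).  Genotypes are complete-data only:
missing entries are a hard error naming the offending cell, because
imputation would silently change cell membership in the search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import GenotypeMatrix
from .errors import InvalidInputError, ParseError
from .survival_core import SurvivalSample

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "write_dataset",
    "read_run_config",
]

PLINK_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Load a genotype matrix.

    ``delimited``: header row of SNP ids, first column the subject id,
    cells in {0, 1, 2}.  ``plink_raw``: the PLINK ``--recode A`` layout
    (FID IID PAT MAT SEX PHENOTYPE followed by one allele-dosage column per
    SNP); IID becomes the subject id and the ``_allele`` suffix is dropped
    from SNP names.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"genotype file not found: {path}")
    if format == "delimited":
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in PLINK_RAW_META if c not in df.columns]
        if missing_meta:
            raise ParseError(f"{path}: not a .raw file; missing {missing_meta}")
        df = df.set_index("IID").drop(columns=[c for c in PLINK_RAW_META if c != "IID"])
        df.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns]
    else:
        raise InvalidInputError(f"unknown genotype format {format!r}")

    subject_ids = [str(s) for s in df.index]
    na = df.isna()
    if na.any().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise ParseError(
            f"{path}: missing genotype at subject {subject_ids[r]!r}, "
            f"SNP {df.columns[c]!r}"
        )
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid genotype {values[r, c]!r} at subject "
            f"{subject_ids[r]!r}, SNP {df.columns[c]!r}"
        )
    try:
        return GenotypeMatrix(values.astype(np.int8), tuple(df.columns), tuple(subject_ids))
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genotypes(path, genotypes: GenotypeMatrix) -> None:
    df = pd.DataFrame(
        genotypes.values,
        index=pd.Index(genotypes.subject_ids, name="subject_id"),
        columns=genotypes.snp_ids,
    )
    df.to_csv(path, sep=_sep(path))


def read_phenotype(
    path,
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: tuple[str, ...] = (),
    subject_order: tuple[str, ...] | None = None,
) -> SurvivalSample:
    """Load a survival phenotype table (first column = subject id).

    When ``subject_order`` is given (normally the genotype file's subject
    ids) the rows are re-aligned to that order; any mismatch in the id sets
    is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.map(str)
    for col in (time_col, status_col, *covariate_cols):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate subject id {dup!r}")
    if subject_order is not None:
        want = [str(s) for s in subject_order]
        missing = set(want) - set(df.index)
        extra = set(df.index) - set(want)
        if missing or extra:
            raise ParseError(
                f"{path}: subject ids do not match genotypes "
                f"(missing {sorted(missing)[:3]}, unexpected {sorted(extra)[:3]})"
            )
        df = df.loc[want]
    time = df[time_col].to_numpy(dtype=float)
    status = df[status_col].to_numpy()
    if np.any(time < 0):
        i = int(np.argmax(time < 0))
        raise ParseError(f"{path}: negative time for subject {df.index[i]!r}")
    if not np.isin(status, (0, 1)).all():
        i = int(np.argmax(~np.isin(status, (0, 1))))
        raise ParseError(
            f"{path}: status {status[i]!r} for subject {df.index[i]!r} "
            "is not 0 or 1"
        )
    cov = df[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
    return SurvivalSample(time, status.astype(np.int8), cov)


def write_phenotype(path, sample: SurvivalSample, subject_ids, covariate_cols=None):
    data = {"time": sample.time, "status": sample.status.astype(int)}
    if sample.covariates is not None:
        names = covariate_cols or [f"z{i + 1}" for i in range(sample.covariates.shape[1])]
        for i, name in enumerate(names):
            data[name] = sample.covariates[:, i]
    df = pd.DataFrame(data, index=pd.Index([str(s) for s in subject_ids], name="subject_id"))
    df.to_csv(path, sep=_sep(path))


def write_dataset(outdir, genotypes, sample, truth=None, prefix="dataset"):
    """Write genotypes + phenotype + JSON metadata sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gpath = outdir / f"{prefix}.genotypes.tsv"
    ppath = outdir / f"{prefix}.phenotype.tsv"
    mpath = outdir / f"{prefix}.meta.json"
    write_genotypes(gpath, genotypes)
    write_phenotype(ppath, sample, genotypes.subject_ids)
    meta = {}
    if truth is not None:
        cfg = truth.get("config")
        pen = truth.get("penetrance")
        meta = {
            "causal_pair": list(truth["causal_pair"]) if truth.get("causal_pair") else None,
            "x": np.asarray(truth["x"]).astype(int).tolist() if "x" in truth else None,
            "censoring_bound": truth.get("censoring_bound"),
            "penetrance": pen.f.tolist() if pen is not None else None,
            "config": _config_dict(cfg) if cfg is not None else None,
        }
    mpath.write_text(json.dumps(meta, indent=2))
    return gpath, ppath, mpath


def _config_dict(cfg) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    pen = d.pop("penetrance", None)
    if pen is not None:
        pen["f"] = np.asarray(pen["f"]).tolist()
    d["penetrance"] = pen
    d["causal_pair"] = list(d["causal_pair"]) if d["causal_pair"] else None
    return d


@dataclass
class RunConfig:
    """Configuration for a full search run (see the CLI)."""

    method: str = "km"
    q_min: int = 2
    q_max: int = 2
    k: int = 10
    cv_repeats: int = 1
    selection_order: str = "test_score_first"
    permutations: int = 0
    seed: int = 0
    genotype_path: str | None = None
    phenotype_path: str | None = None
    genotype_format: str = "delimited"
    time_col: str = "time"
    status_col: str = "status"
    covariate_cols: tuple[str, ...] = ()
    output_dir: str = "."

    def validate(self, p: int | None = None):
        if self.method not in ("km", "surv", "cox", "aft"):
            raise InvalidInputError(f"unknown method {self.method!r}")
        if not (1 <= self.q_min <= self.q_max):
            raise InvalidInputError("need 1 <= q_min <= q_max")
        if p is not None and self.q_max > p:
            raise InvalidInputError(f"q_max={self.q_max} exceeds p={p}")
        if self.k < 2:
            raise InvalidInputError("k must be >= 2")
        if self.permutations < 0:
            raise InvalidInputError("permutations must be >= 0")
        return self


def read_run_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    if "covariate_cols" in raw and raw["covariate_cols"] is not None:
        raw["covariate_cols"] = tuple(raw["covariate_cols"])
    return RunConfig(**raw).validate()
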