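"""File formats, input reconciliation and the end-to-end pipeline.

Everything on disk is tab-delimited text (optionally gzipped) or JSON:

* association results: ``variant_id chrom pos beta se t neg_log10_p p n dof``
  with ``NA`` for flagged/missing values, floats at 17 significant digits;
* per-feature summary statistics: one file per feature
  (``variant_id chrom pos beta se n``) or a single long-format file with a
  ``feature_id`` column;
* covariance: square matrix with feature ids on the first row and column,
  plus a JSON metadata sidecar (``<path>.meta.json``) recording the sample
  size, covariate count (intercept included), divisor and optional
  chromosome key;
* projections: two columns ``feature_id weight`` with an optional
  ``#intercept=`` header line;
* phenotype/genotype matrices: header of column ids, first column of record
  ids.  Anonymized outputs re-issue record ids as row numbers; original ids
  are never emitted.

No command that consumes summary-level inputs ever writes an
individual-level (N-row) matrix to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .gwas_core import AssociationResult, InputError, PartialCovariance
from .indirect_engine import FeatureStatsBlock, Projection, indirect_scan
from .linearizer import LinearApproximation, fit_linear_approximation
from .phenotype_dsl import PhenotypeNode, evaluate

__all__ = [
    "write_association_results",
    "read_association_results",
    "write_feature_stats",
    "read_feature_stats",
    "write_covariance",
    "read_covariance",
    "write_projection",
    "read_projection",
    "write_matrix",
    "read_matrix",
    "RunManifest",
    "write_manifest",
    "load_aligned_inputs",
    "run_definition_pipeline",
]

logger = logging.getLogger("indirectgwas")

_ASSOC_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "t", "neg_log10_p", "p", "n", "dof"]


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

def write_association_results(results: list[AssociationResult], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_ASSOC_COLUMNS) + "\n")
        for r in results:
            if r.flag == "constant-genotype" or r.flag == "inconsistent-inputs":
                beta, se = "NA", "NA"
            else:
                beta, se = _fmt(r.beta), _fmt(r.se)
            t = "NA" if not np.isfinite(r.t) else _fmt(r.t)
            if np.isnan(r.neg_log10_p):
                nlp, p = "NA", "NA"
            elif np.isinf(r.neg_log10_p):
                nlp, p = "inf", "0"
            else:
                nlp, p = _fmt(r.neg_log10_p), _fmt(r.p)
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{beta}\t{se}\t{t}\t{nlp}\t{p}\t{r.n}\t{r.dof}\n"
            )


def read_association_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"variant_id": str, "chrom": str},
                     float_precision="round_trip")
    missing = [c for c in _ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"association file {path} lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Feature summary statistics
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "n"]


def write_feature_stats(block: FeatureStatsBlock, directory: str | Path) -> list[Path]:
    """One tab-delimited file per feature under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, fid in enumerate(block.feature_ids):
        path = directory / f"{fid}.tsv"
        df = pd.DataFrame(
            {
                "variant_id": block.variant_ids,
                "chrom": block.chrom,
                "pos": block.pos,
                "beta": block.b[:, j],
                "se": block.s[:, j],
                "n": block.n[:, j].astype(int),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def _read_one_feature(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"variant_id": str, "chrom": str},
                     float_precision="round_trip")
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns and c not in ("chrom", "pos")]
    if missing:
        raise InputError(f"summary-statistics file {path} lacks columns {missing}")
    return df


def read_feature_stats(paths: list[str | Path] | str | Path) -> FeatureStatsBlock:
    """Read per-feature files (feature id = file stem) or one long-format file
    containing a ``feature_id`` column.  Gzip is handled transparently by the
    ``.gz`` extension.  Variants are intersected across features in the order
    of the first file; dropped variants are logged.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        df = _read_one_feature(path)
        if "feature_id" not in df.columns:
            raise InputError(
                f"{path} has no feature_id column; pass a list of per-feature files instead"
            )
        frames = {str(fid): g.drop(columns="feature_id") for fid, g in df.groupby("feature_id", sort=False)}
    else:
        frames = {}
        for p in paths:
            p = Path(p)
            fid = p.name
            for suffix in (".gz", ".tsv", ".txt"):
                if fid.endswith(suffix):
                    fid = fid[: -len(suffix)]
            frames[fid] = _read_one_feature(p)
    if not frames:
        raise InputError("no summary-statistics inputs given")
    feature_ids = list(frames)
    order = list(frames[feature_ids[0]]["variant_id"])
    shared = set(order)
    for df in frames.values():
        shared &= set(df["variant_id"])
    if not shared:
        raise InputError("no variants shared across all feature summary statistics")
    kept = [v for v in order if v in shared]
    dropped = len(order) - len(kept)
    if dropped:
        logger.info("dropped %d variants absent from some features", dropped)
    V, m = len(kept), len(feature_ids)
    b = np.empty((V, m))
    s = np.empty((V, m))
    n = np.empty((V, m))
    first = frames[feature_ids[0]].set_index("variant_id").loc[kept]
    chrom = [str(c) for c in first["chrom"]] if "chrom" in first else ["0"] * V
    pos = [int(p) for p in first["pos"]] if "pos" in first else list(range(1, V + 1))
    for j, fid in enumerate(feature_ids):
        sub = frames[fid].set_index("variant_id").loc[kept]
        b[:, j] = sub["beta"].to_numpy(dtype=float)
        s[:, j] = sub["se"].to_numpy(dtype=float)
        n[:, j] = sub["n"].to_numpy(dtype=float)
    return FeatureStatsBlock(kept, feature_ids, b, s, n, chrom, pos)


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

def write_covariance(C: PartialCovariance, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(C.values, index=C.feature_ids, columns=C.feature_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="feature_id")
    meta = {
        "n_samples": C.n_samples,
        "n_covariates": C.n_covariates,
        "divisor": C.divisor,
        "chromosome": C.chromosome,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_covariance(path: str | Path) -> PartialCovariance:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    divisor = meta.get("divisor")
    if divisor is None:
        ns = meta.get("n_samples")
        divisor = float(ns - 1) if ns else 1.0
    return PartialCovariance(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        float(divisor),
        meta.get("n_samples"),
        meta.get("n_covariates"),
        meta.get("chromosome"),
    )


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def write_projection(p: Projection, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#intercept={format(p.intercept, '.17g')}\n")
        fh.write("feature_id\tweight\n")
        for fid, w in zip(p.feature_ids, p.weights):
            fh.write(f"{fid}\t{format(w, '.17g')}\n")


def read_projection(path: str | Path, label: str | None = None) -> Projection:
    path = Path(path)
    intercept = 0.0
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if line.startswith("#intercept="):
                    intercept = float(line.split("=", 1)[1])
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    if "feature_id" not in df.columns or "weight" not in df.columns:
        raise InputError(f"projection file {path} needs feature_id and weight columns")
    return Projection(
        [str(f) for f in df["feature_id"]],
        df["weight"].to_numpy(dtype=float),
        intercept=intercept,
        label=label or path.stem,
    )


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(
    X: np.ndarray | pd.DataFrame,
    path: str | Path,
    column_ids: list[str] | None = None,
    record_ids: list[str] | None = None,
) -> None:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.asarray(X)
        if column_ids is None:
            column_ids = [f"x{j + 1}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=column_ids)
    df.index = record_ids if record_ids is not None else range(len(df))
    df.to_csv(path, sep="\t", index_label="record_id", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    inputs: dict[str, str]      # path -> sha256
    seed: int | None
    covariate_count: int | None
    divisor: float | None
    tool_version: str
    timestamp: str


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    input_paths: list[str | Path],
    seed: int | None = None,
    covariate_count: int | None = None,
    divisor: float | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={str(p): _sha256(Path(p)) for p in input_paths if Path(p).exists()},
        seed=seed,
        covariate_count=covariate_count,
        divisor=divisor,
        tool_version=_version,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=1))
    return path


# ---------------------------------------------------------------------------
# Aligned loading and the five-step pipeline
# ---------------------------------------------------------------------------

def load_aligned_inputs(
    sumstats_paths: list[str | Path] | str | Path,
    covariance_path: str | Path,
    projection_path: str | Path,
) -> tuple[FeatureStatsBlock, PartialCovariance, Projection]:
    """Load and reconcile the three indirect-GWAS inputs by feature id.

    Variants are intersected across features in input order; features are the
    intersection order of the summary statistics, checked against the
    covariance matrix; projection features absent from the covariance matrix
    are an error.
    """
    block = read_feature_stats(sumstats_paths)
    C = read_covariance(covariance_path)
    p = read_projection(projection_path)
    missing = [f for f in p.feature_ids if f not in C.feature_ids]
    if missing:
        raise InputError(f"projection features absent from covariance matrix: {missing}")
    missing = [f for f in p.feature_ids if f not in block.feature_ids]
    if missing:
        raise InputError(f"projection features absent from summary statistics: {missing}")
    shared = [f for f in block.feature_ids if f in set(C.feature_ids)]
    if not shared:
        raise InputError("no features shared between summary statistics and covariance matrix")
    return block.align_features(shared), C.subset(shared), p


def run_definition_pipeline(
    definition: PhenotypeNode | str | dict,
    anonymized: pd.DataFrame,
    stats: FeatureStatsBlock,
    C: PartialCovariance,
) -> tuple[dict, list[AssociationResult]]:
    """The five-step flow behind an interactive approximate-GWAS request.

    1. parse the phenotype definition; 2. evaluate it on the (anonymized,
    possibly fractional) feature matrix; 3. linearize the evaluated vector by
    OLS on the same features; 4. report the fit-quality gauge; 5. run
    indirect GWAS with the fitted projection.  Returns the gauge report and
    the association results; total wall time is logged.
    """
    t0 = time.perf_counter()
    if not isinstance(definition, PhenotypeNode):
        from .phenotype_dsl import parse_definition

        definition = parse_definition(definition, registry=set(anonymized.columns))
    y = evaluate(definition, anonymized, fractional=True)
    if np.ptp(y) == 0:
        raise InputError(
            f"definition {definition.to_text()!r} evaluates to a constant vector; "
            "its GWAS is undefined"
        )
    approx: LinearApproximation = fit_linear_approximation(
        y, anonymized.to_numpy(dtype=float), list(anonymized.columns),
        label=definition.to_text(),
    )
    report = {
        "definition": definition.to_text(),
        "r2": approx.r2,
        "n_used": approx.n_used,
        "gauge": approx.gauge,
    }
    results = indirect_scan(stats, C, approx.projection)
    report["wall_time_s"] = time.perf_counter() - t0
    logger.info("definition pipeline finished in %.3f s (gauge=%s, r2=%.3f)",
                report["wall_time_s"], approx.gauge, approx.r2)
    return report, results
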