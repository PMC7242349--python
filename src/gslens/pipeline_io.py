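"""File formats, run configuration and the simulate→detect→treat→predict chain.

Genotypes travel as delimited text (TSV/CSV with a marker header and an ID
column, or a PLINK-RAW-like dialect whose six leading pedigree columns are
skipped), phenotypes as a two-column table joined to the genotypes by
individual ID, and every run writes plain TSV/JSON artifacts that the
module's own readers parse back.  All randomness flows from explicit seeds
in the run configuration, so a pipeline run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError, InputError
from .simulate import MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "GSDataset",
    "RunConfig",
    "read_genotypes",
    "read_phenotypes",
    "read_marker_map",
    "load_dataset",
    "write_genotypes",
    "write_phenotypes",
    "write_marker_map",
    "write_dataset",
    "run_pipeline",
]

_SEP = {"tsv": "\t", "csv": ","}


@dataclass
class GSDataset:
    """Individuals x markers dosage matrix with an aligned phenotype vector."""

    individual_ids: list[str]
    marker_ids: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    marker_map: MarkerMap | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n, p = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise InputError("individual IDs and genotype rows disagree")
        if len(self.marker_ids) != p:
            raise InputError("marker IDs and genotype columns disagree")
        if len(self.phenotype) != n:
            raise InputError("phenotype length differs from the number of individuals")
        if np.isnan(self.genotypes).any() or np.isnan(self.phenotype).any():
            raise InputError("missing values must be imputed or rejected at load time")
        if self.marker_map is not None and len(self.marker_map) != p:
            raise InputError("marker map and genotype columns disagree")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, rows: np.ndarray) -> "GSDataset":
        rows = np.asarray(rows, dtype=int)
        return GSDataset(
            individual_ids=[self.individual_ids[i] for i in rows],
            marker_ids=list(self.marker_ids),
            genotypes=self.genotypes[rows],
            phenotype=self.phenotype[rows],
            marker_map=self.marker_map,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _validate_codes(
    values: pd.DataFrame, allowed: tuple, impute_mean: bool
) -> np.ndarray:
    mat = values.to_numpy()
    # non-numeric cells surface as NaN after coercion but must be distinguished
    coerced = values.apply(pd.to_numeric, errors="coerce")
    bad_text = coerced.isna() & values.notna()
    if bad_text.any().any():
        r, c = np.argwhere(bad_text.to_numpy())[0]
        raise FormatError(
            f"non-numeric genotype cell at row {values.index[r]!r}, column {values.columns[c]!r}"
        )
    mat = coerced.to_numpy(dtype=float)
    missing = np.isnan(mat)
    if missing.any():
        if not impute_mean:
            r, c = np.argwhere(missing)[0]
            raise FormatError(
                f"missing genotype at row {values.index[r]!r}, column {values.columns[c]!r}; "
                "pass impute_mean=True to mean-impute"
            )
        col_means = np.nanmean(mat, axis=0)
        fill = np.take(col_means, np.nonzero(missing)[1])
        mat[missing] = fill
        logger.warning("mean-imputed %d missing genotype cells", int(missing.sum()))
    if allowed is not None:
        bad = ~np.isin(mat, allowed) & ~missing  # imputed cells may be fractional
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"genotype code {mat[r, c]!r} outside {sorted(allowed)} at row "
                f"{values.index[r]!r}, column {values.columns[c]!r}"
            )
    return mat


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    coding: tuple = (0, 1, 2),
    impute_mean: bool = False,
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a genotype table; returns (individual IDs, marker IDs, matrix).

    ``dialect``: 'tsv'/'csv' expect a marker-ID header and an ID first
    column; 'plink_raw' is whitespace-delimited with six leading pedigree
    columns (FID IID PAT MAT SEX PHENOTYPE) and per-marker dosage columns.
    ``coding=None`` disables the code check (dosages are kept as-is).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"genotype file not found: {path}")
    if dialect in _SEP:
        table = pd.read_csv(path, sep=_SEP[dialect], dtype=str)
        if table.shape[1] < 2:
            raise FormatError(f"{path}: expected an ID column plus marker columns")
        ids = table.iloc[:, 0].tolist()
        values = table.iloc[:, 1:]
        values.index = ids
        marker_ids = list(values.columns)
    elif dialect == "plink_raw":
        table = pd.read_csv(path, sep=r"\s+", dtype=str)
        if table.shape[1] < 7:
            raise FormatError(f"{path}: PLINK-RAW needs 6 pedigree columns plus markers")
        ids = table["IID"].tolist() if "IID" in table.columns else table.iloc[:, 1].tolist()
        values = table.iloc[:, 6:]
        values.index = ids
        marker_ids = list(values.columns)
    else:
        raise ConfigurationError(f"unknown genotype dialect {dialect!r}")
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate individual IDs")
    allowed = None if coding is None else tuple(float(c) for c in coding)
    mat = _validate_codes(values, allowed, impute_mean)
    return [str(i) for i in ids], [str(m) for m in marker_ids], mat


def read_phenotypes(path: str | Path, sep: str = "\t") -> pd.Series:
    """Two-column (individual, value) table keyed by individual ID."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"phenotype file not found: {path}")
    table = pd.read_csv(path, sep=sep, dtype=str)
    if table.empty or table.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (individual, value)")
    ids = table.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate individual ID {dup!r}")
    values = pd.to_numeric(table.iloc[:, 1], errors="coerce")
    if values.isna().any():
        bad = table.iloc[:, 1][values.isna()].iloc[0]
        raise FormatError(f"{path}: non-numeric phenotype value {bad!r}")
    return pd.Series(values.to_numpy(dtype=float), index=ids.tolist())


def read_marker_map(path: str | Path, sep: str = "\t") -> tuple[list[str], MarkerMap]:
    table = pd.read_csv(path, sep=sep)
    required = {"marker", "chromosome", "cM"}
    if not required <= set(table.columns):
        raise FormatError(f"{path}: marker map needs columns {sorted(required)}")
    return (
        table["marker"].astype(str).tolist(),
        MarkerMap(
            chromosome=table["chromosome"].to_numpy(dtype=int),
            position_cm=table["cM"].to_numpy(dtype=float),
        ),
    )


def load_dataset(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    dialect: str = "tsv",
    coding: tuple = (0, 1, 2),
    impute_mean: bool = False,
    marker_map_path: str | Path | None = None,
) -> GSDataset:
    """Load and join genotypes and phenotypes by individual ID."""
    ids, marker_ids, mat = read_genotypes(genotype_path, dialect, coding, impute_mean)
    pheno = read_phenotypes(phenotype_path)
    missing = [i for i in ids if i not in pheno.index]
    if missing:
        raise InputError(f"no phenotype for individual(s): {missing[:5]}")
    marker_map = None
    if marker_map_path is not None:
        _, marker_map = read_marker_map(marker_map_path)
    return GSDataset(
        individual_ids=ids,
        marker_ids=marker_ids,
        genotypes=mat,
        phenotype=pheno.loc[ids].to_numpy(),
        marker_map=marker_map,
    )


_FLOAT_FMT = "%.10g"


def write_genotypes(dataset: GSDataset, path: str | Path) -> None:
    frame = pd.DataFrame(
        dataset.genotypes, index=dataset.individual_ids, columns=dataset.marker_ids
    )
    frame.index.name = "individual"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_phenotypes(dataset: GSDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"individual": dataset.individual_ids, "value": dataset.phenotype}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_marker_map(dataset: GSDataset, path: str | Path) -> None:
    if dataset.marker_map is None:
        raise InputError("dataset carries no marker map")
    pd.DataFrame(
        {
            "marker": dataset.marker_ids,
            "chromosome": dataset.marker_map.chromosome,
            "cM": dataset.marker_map.position_cm,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_dataset(dataset: GSDataset, outdir: str | Path, truth=None) -> dict:
    """Write genotypes/phenotypes (and map/truth when present); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    write_genotypes(dataset, paths["genotypes"])
    write_phenotypes(dataset, paths["phenotypes"])
    if dataset.marker_map is not None:
        paths["marker_map"] = outdir / "marker_map.tsv"
        write_marker_map(dataset, paths["marker_map"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run.

    ``simulation`` (when present) holds :class:`~gslens.simulate.SimulationConfig`
    fields; otherwise ``data`` must name genotype/phenotype files.  Every
    stochastic stage carries an explicit seed.
    """

    simulation: dict | None = None
    data: dict | None = None
    influence: dict = field(default_factory=dict)
    combine: dict = field(default_factory=lambda: {"method": "fisher", "alpha": 0.05})
    treatment: str = "delete"
    models: list = field(default_factory=lambda: [{"kind": "lasso"}])
    evaluation: dict = field(
        default_factory=lambda: {"n_rep": 100, "train_frac": 0.7, "seed": 0}
    )
    rank: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None and self.data is None:
            raise ConfigurationError("config must provide either 'simulation' or 'data'")
        if self.treatment not in ("none", "delete", "msom-indicator", "msom-replace"):
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        if "seed" not in self.evaluation:
            raise ConfigurationError("evaluation.seed is required")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute detect → treat → predict → evaluate (→ rank) and write artifacts.

    The untreated LASSO fit is the baseline row, labeled ``LASSO*`` with
    blank gain/reduction; every other model row reports percentage gain in
    accuracy and percentage reduction in MSE against it.  A manifest JSON
    records seeds, stage parameters and output hashes.
    """
    from . import combine as combine_mod
    from . import evaluate as evaluate_mod
    from . import gs_models, influence, simulate

    import time

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}}

    stage = "data"
    t_stage = time.perf_counter()

    def _done(name: str) -> None:
        nonlocal t_stage
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t_stage)
        t_stage = time.perf_counter()

    try:
        if config.simulation is not None:
            sim_cfg = simulate.SimulationConfig(**config.simulation)
            dataset, truth = simulate.simulate_dataset(sim_cfg)
            write_dataset(dataset, outdir, truth)
            manifest["stages"][stage] = {"simulation": dataclasses.asdict(sim_cfg)}
        else:
            dataset = load_dataset(**config.data)
            manifest["stages"][stage] = {"data": dict(config.data)}
        _done(stage)

        stage = "detect"
        inf_cfg = influence.InfluenceConfig(**config.influence)
        table = influence.influence_table(
            dataset.genotypes, dataset.phenotype, inf_cfg, dataset.individual_ids
        )
        table.frame.to_csv(
            outdir / "influence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        (outdir / "influence_meta.json").write_text(json.dumps(table.metadata, indent=2))
        method = config.combine.get("method", "fisher")
        alpha = config.combine.get("alpha", 0.05)
        methods = combine_mod.ALL_METHODS if method == "all" else (method,)
        combined = combine_mod.combine_pvalues(
            table.pvalue_matrix(tuple(inf_cfg.measures)),
            methods=methods,
            alpha=alpha,
            observation_ids=dataset.individual_ids,
        )
        combined.frame.to_csv(
            outdir / "combined.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        flag_method = methods[0]
        flagged = combined.flagged_set(flag_method)
        pd.DataFrame(
            {"individual": [dataset.individual_ids[i] for i in flagged]}
        ).to_csv(outdir / "flags.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "influence": dataclasses.asdict(inf_cfg),
            "combine": {"methods": list(methods), "alpha": alpha, "flag_method": flag_method},
            "n_flagged": int(len(flagged)),
        }
        _done(stage)

        stage = "treat"
        X, y = dataset.genotypes, dataset.phenotype
        if config.treatment == "delete" and len(flagged):
            treated = gs_models.delete_treat(X, y, flagged)
            Xt, yt = treated.X, treated.y
        elif config.treatment.startswith("msom") and len(flagged):
            mode = config.treatment.split("-", 1)[1]
            treated = gs_models.msom_treat(X, y, flagged, mode=mode)
            Xt, yt = treated.X, treated.y
        else:
            Xt, yt = X, y
        manifest["stages"][stage] = {"treatment": config.treatment}
        _done(stage)

        stage = "evaluate"
        ev = config.evaluation
        baseline = evaluate_mod.cv_protocol(
            X,
            y,
            gs_models.LassoModel,
            n_rep=ev.get("n_rep", 100),
            train_frac=ev.get("train_frac", 0.7),
            seed=ev["seed"],
            model_name="LASSO*",
            treatment="none",
        )
        rows = [
            {**baseline.summary(), "gain_pct": None, "mse_reduction_pct": None}
        ]
        for spec in config.models:
            kind = spec["kind"]
            params = {k: v for k, v in spec.items() if k != "kind"}
            report = evaluate_mod.cv_protocol(
                Xt,
                yt,
                lambda: gs_models.make_model(kind, **params),
                n_rep=ev.get("n_rep", 100),
                train_frac=ev.get("train_frac", 0.7),
                seed=ev["seed"],
                model_name=kind,
                treatment=config.treatment,
            )
            gain, reduction = evaluate_mod.pct_change(report, baseline)
            rows.append(
                {**report.summary(), "gain_pct": gain, "mse_reduction_pct": reduction}
            )
        report_frame = pd.DataFrame(rows)
        report_frame.to_csv(
            outdir / "report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        manifest["stages"][stage] = {"evaluation": dict(ev)}
        _done(stage)

        if config.rank and len(report_frame) >= 2:
            stage = "rank"
            crit = report_frame[["accuracy", "mse", "accuracy_se", "mse_se"]].copy()
            crit.index = report_frame["model"]
            ranking = evaluate_mod.topsis(crit, impacts=["+", "-", "-", "-"])
            ranking.to_csv(outdir / "ranking.tsv", sep="\t", float_format=_FLOAT_FMT)
            manifest["stages"][stage] = {"criteria": list(crit.columns)}
            _done(stage)
    except Exception:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.error("pipeline failed during stage %r; partial outputs kept", stage)
        raise

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) if p.is_file()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
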