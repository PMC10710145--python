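"""File I/O, configuration, and the end-to-end pipeline driver.

All delimited files are tab-separated UTF-8 with "NA" for missing values.
Genotypes are read either from a delimited additive-coding table (subjects x
SNPs, header row of variant ids, first column the subject id) or from a VCF
whose GT fields are mapped to minor-allele counts (via cyvcf2).  Feature
tables (views) and the phenotype/covariate table share the delimited layout.
Subjects are aligned across all inputs by id intersection.

``run_pipeline`` ties the stages together: QC -> genotype PCA -> GWAS ->
top-K SNP selection -> train/test split -> per-view min-max scaling ->
MVAE-PoE training -> linear regression head -> evaluation -> leave-one-out
importance.  Every stage draws its seed from one global seed so each output
is reproducible in isolation, and a manifest records the seed and a config
hash.
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

from .gwas import (
    CovariateSet,
    GenotypeMatrix,
    QCThresholds,
    genotype_pca,
    qc_filter,
    run_gwas,
    select_top_k,
)
from .interpret import loo_importance
from .mvae import save_params
from .train import (
    TrainConfig,
    apply_scaler,
    evaluate,
    extract_latents,
    fit_head,
    fit_scaler,
    predict,
    split_train_test,
    train_mvae,
)

__all__ = [
    "PipelineConfig",
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_feature_table",
    "write_feature_table",
    "align_subjects",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_SEP = "\t"
_NA = "NA"
_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths plus per-stage settings for one pipeline run.

    ``view_paths`` maps view name -> feature-table path; ``use_wgs``
    controls whether the selected-SNP view enters the model (disabling it,
    or supplying a single view, degrades the MVAE-PoE to a standard
    single-view VAE).
    """

    genotype_path: str = ""
    genotype_format: str = "delimited"  # or "vcf"
    phenotype_path: str = ""
    phenotype_column: str = "phenotype"
    covariate_columns: tuple = ("age", "weight", "height")
    view_paths: dict = field(default_factory=dict)
    use_wgs: bool = True
    output_dir: str = "mvfuse_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    top_k: int = 256
    n_pcs: int = 10
    train: TrainConfig = field(default_factory=TrainConfig)
    importance_top_k: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCThresholds(**raw.pop("qc", {}))
        train = TrainConfig(**raw.pop("train", {}))
        if "covariate_columns" in raw:
            raw["covariate_columns"] = tuple(raw["covariate_columns"])
        return cls(qc=qc, train=train, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_columns"] = list(self.covariate_columns)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def write_genotypes(genotypes: GenotypeMatrix, path, meta_path=None):
    """Delimited additive-coding table; variant metadata sidecar optional."""
    df = pd.DataFrame(
        genotypes.counts, index=genotypes.subject_ids, columns=genotypes.variant_ids
    )
    df.index.name = "subject_id"
    out = df.map(lambda v: _NA if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=_SEP)
    if meta_path is not None:
        pd.DataFrame(
            {
                "variant_id": genotypes.variant_ids,
                "chrom": genotypes.chromosome,
                "pos": genotypes.position,
            }
        ).to_csv(meta_path, sep=_SEP, index=False)


def write_vcf(genotypes: GenotypeMatrix, path):
    """Minimal single-sample-per-column VCF with GT fields only.

    Alleles are placeholders (A/G); only the additive coding matters here.
    """
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(int(x) for x in genotypes.chromosome)):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(str(s) for s in genotypes.subject_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, vid in enumerate(genotypes.variant_ids):
            gts = "\t".join(
                "./." if np.isnan(v) else gt_of[v] for v in genotypes.counts[:, j]
            )
            fh.write(
                f"{int(genotypes.chromosome[j])}\t{int(genotypes.position[j])}\t{vid}"
                f"\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_genotypes_delimited(path, meta_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=_SEP, index_col=0, dtype=str, na_values=[_NA])
    counts = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            if pd.isna(val):
                continue
            if val not in ("0", "1", "2"):
                raise ValueError(
                    f"invalid genotype '{val}' at row {df.index[i]!r}, column {col!r}"
                )
            counts[i, j] = float(val)
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path, sep=_SEP)
        chrom = meta["chrom"].to_numpy()
        pos = meta["pos"].to_numpy()
    else:
        chrom = np.ones(df.shape[1], dtype=int)
        pos = 1 + np.arange(df.shape[1])
    return GenotypeMatrix(
        counts=counts,
        subject_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
        chromosome=chrom,
        position=pos,
    )


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols, vids, chroms, poss = [], [], [], []
    for var in vcf:
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        gt[gt == 2] = np.nan
        gt[gt == 3] = 2.0
        cols.append(gt)
        vids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(int(var.CHROM))
        poss.append(var.POS)
    vcf.close()
    return GenotypeMatrix(
        counts=np.column_stack(cols),
        subject_ids=subjects,
        variant_ids=vids,
        chromosome=np.asarray(chroms),
        position=np.asarray(poss),
    )


def read_genotypes(path, fmt: str = "delimited", meta_path=None) -> GenotypeMatrix:
    """Read genotypes from a delimited additive table or a VCF."""
    if fmt == "delimited":
        return _read_genotypes_delimited(path, meta_path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format '{fmt}'")


# ---------------------------------------------------------------------------
# Feature tables and alignment
# ---------------------------------------------------------------------------

def write_feature_table(matrix, subject_ids, feature_names, path):
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=subject_ids,
                      columns=feature_names)
    df.index.name = "subject_id"
    df.to_csv(path, sep=_SEP, float_format=_FLOAT_FMT, na_rep=_NA)


def read_feature_table(path) -> pd.DataFrame:
    """Subject-indexed real-valued table (header row of feature names,
    first column subject id); duplicate subject ids are rejected."""
    df = pd.read_csv(path, sep=_SEP, index_col=0, na_values=[_NA])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids: {dupes[:5]}")
    return df


def align_subjects(tables: dict) -> dict:
    """Restrict every table to the id intersection, in a common order."""
    ids = None
    for name, df in tables.items():
        ids = set(df.index) if ids is None else ids & set(df.index)
    if not ids:
        raise ValueError("no subjects shared across all inputs")
    dropped = {name: len(df) - len(ids) for name, df in tables.items()}
    if any(dropped.values()):
        logger.warning("dropped subjects absent from some input: %s", dropped)
    order = sorted(ids)
    return {name: df.loc[order] for name, df in tables.items()}


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return round(float(o), 10)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write its artifacts.

    Outputs in ``config.output_dir``: association.tsv (score-test table),
    selected_variants.tsv, selected_features.tsv, model.npz, metrics.json,
    importance.tsv, importance_top.tsv, qc_report.json and manifest.json.
    Raises with the failing stage's name; artifacts written so far persist.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        genotypes = read_genotypes(
            config.genotype_path, config.genotype_format,
            meta_path=str(config.genotype_path) + ".meta",
        )
        pheno_df = read_feature_table(config.phenotype_path)
        view_dfs = {name: read_feature_table(p) for name, p in config.view_paths.items()}

        tables = {"__genotypes__": pd.DataFrame(index=pd.Index(
            [str(s) for s in genotypes.subject_ids], name="subject_id")),
            "__phenotype__": pheno_df, **view_dfs}
        aligned = align_subjects(tables)
        order = list(aligned["__phenotype__"].index)
        gidx = [genotypes.subject_ids.index(s) for s in order]
        genotypes = genotypes.take_subjects(np.asarray(gidx))
        pheno_df = aligned["__phenotype__"]
        view_dfs = {n: aligned[n] for n in view_dfs}

        phenotype = pheno_df[config.phenotype_column].to_numpy(dtype=float)
        base_cov = pheno_df[list(config.covariate_columns)].to_numpy(dtype=float)

        stage = "qc"
        genotypes, qc_report = qc_filter(genotypes, config.qc)
        kept = set(genotypes.subject_ids)
        keep_mask = np.array([s in kept for s in order])
        phenotype = phenotype[keep_mask]
        base_cov = base_cov[keep_mask]
        view_dfs = {n: df.loc[keep_mask] for n, df in view_dfs.items()}
        _write_json(
            {
                "removed_subjects": [
                    {"id": s, "reasons": r, "stats": st}
                    for s, r, st in qc_report.removed_subjects
                ],
                "removed_variants": [
                    {"id": v, "reasons": r, "stats": st}
                    for v, r, st in qc_report.removed_variants
                ],
            },
            out / "qc_report.json",
        )

        stage = "pca"
        pcs = genotype_pca(genotypes, config.n_pcs)
        covariates = CovariateSet(
            matrix=np.column_stack([base_cov, pcs]),
            names=list(config.covariate_columns)
            + [f"PC{i+1}" for i in range(config.n_pcs)],
        )

        stage = "gwas"
        table = run_gwas(genotypes, phenotype, covariates)
        table.to_csv(out / "association.tsv", sep=_SEP, index=False,
                     float_format=_FLOAT_FMT)

        stage = "select"
        k = min(config.top_k, len(table))
        selected_ids, wgs_features = select_top_k(table, genotypes, k)
        pd.DataFrame({"variant_id": selected_ids}).to_csv(
            out / "selected_variants.tsv", sep=_SEP, index=False
        )
        write_feature_table(
            wgs_features, genotypes.subject_ids, selected_ids,
            out / "selected_features.tsv",
        )

        stage = "assemble_views"
        views, view_names = [], []
        if config.use_wgs:
            views.append(wgs_features)
            view_names.append("wgs")
        for name, df in view_dfs.items():
            views.append(df.to_numpy(dtype=float))
            view_names.append(name)
        if not views:
            raise ValueError("no views enabled")
        feature_names = (
            [selected_ids] if config.use_wgs else []
        ) + [list(df.columns) for df in view_dfs.values()]

        stage = "split_scale"
        n = phenotype.size
        train_idx, test_idx = split_train_test(
            n, config.train.test_fraction, seed=_stage_seed(config.seed, 1)
        )
        train_views = [v[train_idx] for v in views]
        test_views = [v[test_idx] for v in views]
        scaler = fit_scaler(train_views)
        train_scaled = apply_scaler(scaler, train_views)
        test_scaled = apply_scaler(scaler, test_views)

        stage = "train"
        tcfg = dataclasses.replace(config.train, seed=_stage_seed(config.seed, 2))
        params, trace = train_mvae(train_scaled, tcfg, view_names=view_names)
        save_params(params, out / "model.npz")

        stage = "head"
        z_train = extract_latents(params, train_scaled, view_names)
        head = fit_head(z_train, phenotype[train_idx])

        stage = "evaluate"
        z_test = extract_latents(params, test_scaled, view_names)
        report = evaluate(phenotype[test_idx], predict(head, z_test))
        metrics = {
            "mae": report.mae,
            "mape_pct": report.mape,
            "rmse": report.rmse,
            "r2": report.r2,
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
            "final_epoch_loss": float(trace[-1]),
            "views": view_names,
        }
        _write_json(metrics, out / "metrics.json")
        pd.DataFrame(report.pairs, columns=["y", "yhat"]).to_csv(
            out / "predictions.tsv", sep=_SEP, index=False, float_format=_FLOAT_FMT
        )

        stage = "importance"
        ranking = loo_importance(
            params, head, scaler, test_views, phenotype[test_idx],
            view_names=view_names, feature_names=feature_names,
            top_k=config.importance_top_k,
        )
        ranking.to_csv(out / "importance.tsv", sep=_SEP, index=False,
                       float_format=_FLOAT_FMT)
        ranking.attrs["top"].to_csv(out / "importance_top.tsv", sep=_SEP,
                                    index=False, float_format=_FLOAT_FMT)

        stage = "manifest"
        _write_json(
            {"seed": config.seed, "config": config.to_dict(),
             "config_digest": config.digest(),
             "stage_seeds": {"split": _stage_seed(config.seed, 1),
                             "train": _stage_seed(config.seed, 2)}},
            out / "manifest.json",
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out
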