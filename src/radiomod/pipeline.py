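"""Cohort I/O, configuration, and the end-to-end discovery/validation pipeline.

Cohorts travel either as a single bundle spreadsheet (one row per patient,
radiomic columns prefixed ``radiomic_``, expression columns by gene symbol,
clinical columns ``os_time``/``os_event``/``stage``/``histology``) plus a GMT
gene-set file, or as split CSV files.  The pipeline runs association-matrix
construction on the discovery cohort, module discovery with validation on the
independent cohort, clinical meta-analysis over both, pathway predictors and
the prognostic signature (train on discovery, validate on the other), all
under a single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clinical_mod
from . import enrichment, modules, signatures
from .simulate import CohortBundle

logger = logging.getLogger(__name__)

RADIOMIC_PREFIX = "radiomic_"
CLINICAL_COLS = ("os_time", "os_event", "stage", "histology")


# ---------------------------------------------------------------------------
# Standard formats
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a tab-delimited GMT gene-set file (id, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{line_no}: malformed GMT line")
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            fh.write("\t".join([set_id, description, *sets[set_id]]) + "\n")


def read_volume(path):
    """Read an NRRD or NIfTI volume into (array (z,y,x), spacing_mm, origin)."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def write_volume(arr: np.ndarray, spacing_mm, path, origin_mm=(0.0, 0.0, 0.0)):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(arr))
    img.SetSpacing(tuple(reversed([float(s) for s in spacing_mm])))
    img.SetOrigin(tuple(reversed([float(o) for o in origin_mm])))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Cohort bundles
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, out_dir, layout: str = "bundle_spreadsheet"):
    """Serialize a cohort in the layout the pipeline reads back."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    if layout == "bundle_spreadsheet":
        feat = bundle.features.add_prefix(RADIOMIC_PREFIX)
        expr = bundle.expression.T  # patients x genes
        table = pd.concat([feat, expr, bundle.clinical], axis=1)
        table.index.name = "patient_id"
        table.to_csv(out / "cohort.csv")
    elif layout == "split_files":
        bundle.features.rename_axis("patient_id").to_csv(out / "features.csv")
        bundle.expression.rename_axis("gene").to_csv(out / "expression.csv")
        bundle.clinical.rename_axis("patient_id").to_csv(out / "clinical.csv")
    else:
        raise ValueError(f"unknown layout {layout}")


def load_cohort(path, layout: str = "bundle_spreadsheet", cohort_id: str = "cohort") -> CohortBundle:
    """Load and align one cohort; patients missing any block are dropped.

    Raises on duplicated patient ids or an empty aligned intersection; the
    number of dropped patients is logged (real cohorts have unequal blocks,
    e.g. imaging/expression present but clinical missing).
    """
    p = Path(path)
    gene_sets = read_gmt(p / "gene_sets.gmt")
    if layout == "bundle_spreadsheet":
        try:
            table = pd.read_csv(p / "cohort.csv", index_col="patient_id")
        except ValueError as exc:
            raise ValueError(f"malformed cohort spreadsheet: {exc}") from exc
        rad_cols = [c for c in table.columns if c.startswith(RADIOMIC_PREFIX)]
        clin_cols = [c for c in CLINICAL_COLS if c in table.columns]
        gene_cols = [
            c for c in table.columns if c not in rad_cols and c not in clin_cols
        ]
        features = table[rad_cols].rename(
            columns=lambda c: c[len(RADIOMIC_PREFIX):]
        )
        expression = table[gene_cols].T
        clinical = table[clin_cols]
    elif layout == "split_files":
        features = pd.read_csv(p / "features.csv", index_col="patient_id")
        expression = pd.read_csv(p / "expression.csv", index_col="gene")
        clinical = pd.read_csv(p / "clinical.csv", index_col="patient_id")
    else:
        raise ValueError(f"unknown layout {layout}")

    for name, idx in (
        ("features", features.index),
        ("expression", expression.columns),
        ("clinical", clinical.index),
    ):
        if idx.duplicated().any():
            raise ValueError(f"duplicated patient ids in {name} block")

    _check_numeric(features, "features")
    _check_numeric(expression, "expression")

    aligned = features.index.intersection(expression.columns).intersection(
        clinical.dropna(subset=[c for c in ("os_time", "os_event") if c in clinical]).index
    )
    if len(aligned) == 0:
        raise ValueError("no patient present in all cohort blocks")
    n_dropped = (
        len(set(features.index) | set(expression.columns) | set(clinical.index))
        - len(aligned)
    )
    if n_dropped:
        logger.info("%s: dropped %d patients missing a block", cohort_id, n_dropped)
    return CohortBundle(
        features=features.loc[aligned],
        expression=expression.loc[:, aligned],
        gene_sets=gene_sets,
        clinical=clinical.loc[aligned],
        cohort_id=cohort_id,
    )


def _check_numeric(df: pd.DataFrame, block: str) -> None:
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index
        where = row[0] if len(row) else "?"
        raise ValueError(
            f"malformed numeric cell in {block} block, column {col!r}, row {where!r}"
        )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus the single global seed.

    Every random draw in the pipeline is derived from ``seed``; a rerun
    with the same config and cohorts is bit-identical.
    """

    n_perm_gsea: int = 1000
    gsea_weight: float = 1.0
    min_set_size: int = 15
    max_set_size: int = 500
    isa_row_thresholds: tuple = (1.5, 2.0, 2.5)
    isa_col_thresholds: tuple = (1.5, 2.0, 2.5)
    isa_n_seeds: int = 100
    module_max_corr: float = 0.3
    n_perm_validation: int = 1000
    n_perm_clinical: int = 1000
    signature_max_size: int = 15
    signature_n_cv: int = 1000
    signature_mrmr_k: int = 15
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    association_matrix: pd.DataFrame
    modules: list
    clinical_results: pd.DataFrame
    predictors: list
    strongest_per_module: dict
    signature: signatures.SurvivalSignature | None
    signature_validation_ci: float
    config_hash: str


def run_pipeline(d1: CohortBundle, d2: CohortBundle, cfg: PipelineConfig) -> PipelineResult:
    """Discovery on d1, validation on d2, per the two-cohort design.

    Stages: NES association matrix on d1 -> ISA modules (validated on d2)
    -> clinical associations (both cohorts + meta) -> pathway predictors
    (train d1, validate d2) -> mRMR+Cox signature (train d1, validate d2).
    Stage failures surface with a stage-tagged message.
    """
    rng = np.random.default_rng(cfg.seed)

    def stage_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    collection = _stage(
        "filter_gene_sets",
        lambda: enrichment.filter_gene_sets(
            d1.gene_sets, d1.expression.index, cfg.min_set_size, cfg.max_set_size
        ),
    )
    assoc = _stage(
        "associate",
        lambda: enrichment.build_association_matrix(
            d1.features,
            d1.expression,
            collection,
            n_perm=cfg.n_perm_gsea,
            seed=stage_seed(),
            weight_exp=cfg.gsea_weight,
        ),
    )
    d1_scores = _stage(
        "pathway_scores_d1",
        lambda: enrichment.pathway_score_table(d1.expression, collection),
    )
    d2_scores = _stage(
        "pathway_scores_d2",
        lambda: enrichment.pathway_score_table(d2.expression, collection),
    )
    mods = _stage(
        "modules",
        lambda: modules.discover_and_validate(
            assoc,
            d1.features,
            d1_scores,
            d2.features,
            d2_scores,
            row_thresholds=cfg.isa_row_thresholds,
            col_thresholds=cfg.isa_col_thresholds,
            n_seeds=cfg.isa_n_seeds,
            n_perm=cfg.n_perm_validation,
            max_corr=cfg.module_max_corr,
            seed=stage_seed(),
            cohort_of_origin=d1.cohort_id,
        ),
    )
    clin = _stage(
        "clinical",
        lambda: clinical_mod.assess_modules_clinical(
            mods,
            d1.features,
            d1.clinical,
            d2.features,
            d2.clinical,
            n_perm=cfg.n_perm_clinical,
            seed=stage_seed(),
        ),
    )

    def _predictors():
        preds = []
        strongest = {}
        for mod in mods:
            mod_preds = []
            for set_id in mod.pathway_ids:
                labels1 = signatures.pathway_activation_labels(d1_scores[set_id])
                if labels1.nunique() < 2:
                    continue
                for feat in mod.feature_ids:
                    pred = signatures.fit_univariate_predictor(
                        d1.features[feat], labels1, feature_id=feat, set_id=set_id
                    )
                    mod_preds.append(pred)
            if not mod_preds:
                continue
            best = signatures.strongest_predictor(mod_preds)
            labels2 = signatures.pathway_activation_labels(d2_scores[best.set_id])
            if labels2.nunique() == 2:
                probs = best.predict_proba(
                    d2.features.loc[labels2.index, best.feature_id].to_numpy()
                )
                best.auc_val, _ = signatures.auc_with_noether(
                    probs, labels2.to_numpy()
                )
            preds.extend(mod_preds)
            strongest[mod.module_id] = best
        return preds, strongest

    preds, strongest = _stage("predict", _predictors)

    def _signature():
        ranked = signatures.mrmr_rank(
            d1.features,
            d1.clinical["os_time"].to_numpy(dtype=float),
            d1.clinical["os_event"].to_numpy(dtype=bool),
            k=cfg.signature_mrmr_k,
        )
        sig = signatures.incremental_cox(
            ranked,
            d1.features,
            d1.clinical,
            n_cv=cfg.signature_n_cv,
            seed=stage_seed(),
            max_size=cfg.signature_max_size,
        )
        ci = signatures.validate_signature(sig, d2.features, d2.clinical)
        return sig, ci

    sig, sig_ci = _stage("signature", _signature)

    return PipelineResult(
        association_matrix=assoc,
        modules=mods,
        clinical_results=clin,
        predictors=preds,
        strongest_per_module=strongest,
        signature=sig,
        signature_validation_ci=sig_ci,
        config_hash=cfg.config_hash(),
    )


def write_results(result: PipelineResult, out_dir) -> None:
    """Persist every pipeline artifact as CSV/JSON with provenance headers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"# config_hash={result.config_hash}\n"

    def _csv(df: pd.DataFrame, name: str):
        with open(out / name, "w") as fh:
            fh.write(tag)
            df.to_csv(fh)

    _csv(result.association_matrix, "association_matrix.csv")
    _csv(result.clinical_results, "clinical_associations.csv")
    modules.modules_to_json(result.modules, out / "modules.json")
    _csv(modules.overlap_edge_list(result.modules).set_index("module_a"), "module_overlap.csv")
    with open(out / "signature.json", "w") as fh:
        payload = {
            "config_hash": result.config_hash,
            "feature_ids": result.signature.feature_ids if result.signature else [],
            "coefficients": result.signature.coefficients if result.signature else [],
            "cv_mean_ci": result.signature.cv_mean_ci if result.signature else None,
            "validation_ci": result.signature_validation_ci,
        }
        json.dump(payload, fh, indent=2)
    with open(out / "predictors.json", "w") as fh:
        json.dump(
            {
                mid: dataclasses.asdict(p)
                for mid, p in result.strongest_per_module.items()
            },
            fh,
            indent=2,
        )
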