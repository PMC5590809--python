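"""Frozen synthetic study conditions for end-to-end verification.

These designs define the cohorts on which the pipeline's planted-structure
recovery is measured — the module-recovery study (a coherent block of
radiomic features and pathways planted into a two-cohort design) and the
prognostic-signature study (one feature tied to the hazard).  The conditions
are part of the package's verification contract and are used by both the
test suite and the reproduction script; they are not tuning knobs.
"""

from __future__ import annotations

import numpy as np

from . import enrichment, modules, signatures
from .simulate import PlantedDesign, default_gene_sets, gen_cohort

# Module-recovery study: 150 patients, 50 radiomic features, 500 genes in
# 25 disjoint 15-gene sets; the planted module ties 6 features to 2 pathways
# through one latent factor at correlation 0.6 (a strong radiogenomic
# effect); one of the planted features also carries a log(2) hazard.
MODULE_STUDY = dict(
    n_patients=150,
    n_features=50,
    n_genes=500,
    n_sets=25,
    set_size=15,
    n_planted_features=6,
    n_planted_sets=2,
    strength=0.6,
    censor_rate=0.3,
)

PLANTED_FEATURES = tuple(f"feat_{i}" for i in range(MODULE_STUDY["n_planted_features"]))
PLANTED_SETS = tuple(f"SET{j:03d}" for j in range(MODULE_STUDY["n_planted_sets"]))


def module_study_design(seed: int, null: bool = False) -> PlantedDesign:
    c = MODULE_STUDY
    gene_sets = default_gene_sets(n_sets=c["n_sets"], set_size=c["set_size"])
    links = (
        ()
        if null
        else tuple(
            (f, s, c["strength"]) for f in PLANTED_FEATURES for s in PLANTED_SETS
        )
    )
    n_noise = c["n_features"] - (0 if null else c["n_planted_features"])
    return PlantedDesign(
        n_patients=c["n_patients"],
        n_genes=c["n_genes"],
        gene_sets=gene_sets,
        links=links,
        n_noise_features=n_noise,
        survival_link=("feat_0", np.log(2)) if not null else ("", 0.0),
        censor_rate=c["censor_rate"],
        seed=seed,
    )


def run_module_recovery(
    seed: int,
    null: bool = False,
    n_perm_gsea: int = 300,
    isa_n_seeds: int = 200,
    n_perm_validation: int = 1000,
) -> tuple[bool, int]:
    """One two-cohort replicate of module discovery + validation.

    Returns (planted module among validated at q < 0.05, number validated).
    Recovery means a validated module sharing at least two planted features
    and at least one planted pathway.
    """
    d1 = gen_cohort(module_study_design(2 * seed, null), "d1")
    d2 = gen_cohort(module_study_design(2 * seed + 1, null), "d2")
    coll = enrichment.filter_gene_sets(d1.gene_sets, d1.expression.index)
    assoc = enrichment.build_association_matrix(
        d1.features, d1.expression, coll, n_perm=n_perm_gsea, seed=seed
    )
    s1 = enrichment.pathway_score_table(d1.expression, coll)
    s2 = enrichment.pathway_score_table(d2.expression, coll)
    mods = modules.discover_and_validate(
        assoc,
        d1.features,
        s1,
        d2.features,
        s2,
        n_seeds=isa_n_seeds,
        n_perm=n_perm_validation,
        seed=seed + 10_000,
    )
    validated = [m for m in mods if m.q_fdr < 0.05]
    found = any(
        len(set(m.feature_ids) & set(PLANTED_FEATURES)) >= 2
        and len(set(m.pathway_ids) & set(PLANTED_SETS)) >= 1
        for m in validated
    )
    return found, len(validated)


# Signature study: one planted prognostic feature (hazard log 2 per SD)
# among 9 noise features, 150 patients, 30% censoring.
SIGNATURE_STUDY = dict(
    n_patients=150, n_noise_features=9, hazard=np.log(2), censor_rate=0.3
)


def signature_study_design(seed: int) -> PlantedDesign:
    c = SIGNATURE_STUDY
    return PlantedDesign(
        n_patients=c["n_patients"],
        n_genes=50,
        gene_sets=default_gene_sets(n_sets=2, set_size=15),
        links=(),
        n_noise_features=c["n_noise_features"],
        survival_link=("prog", c["hazard"]),
        censor_rate=c["censor_rate"],
        seed=seed,
    )


def run_signature_recovery(seed: int, n_cv: int = 30) -> tuple[bool, float]:
    """One replicate: mRMR + incremental Cox on a planted-hazard cohort.

    Returns (planted feature in signature, validation CI on an independent
    cohort of the same design).
    """
    d1 = gen_cohort(signature_study_design(2 * seed), "train")
    d2 = gen_cohort(signature_study_design(2 * seed + 1), "val")
    ranked = signatures.mrmr_rank(
        d1.features,
        d1.clinical["os_time"].to_numpy(dtype=float),
        d1.clinical["os_event"].to_numpy(dtype=bool),
        k=5,
    )
    sig = signatures.incremental_cox(
        ranked, d1.features, d1.clinical, n_cv=n_cv, seed=seed, max_size=5
    )
    ci = signatures.validate_signature(sig, d2.features, d2.clinical)
    return ("prog" in sig.feature_ids), ci


def run_fusion_replicate(seed: int):
    """Fused clinical+gene+radiomic Cox vs each single component.

    Three independent standard-normal risk components each carry a 0.6
    log-hazard contribution; returns the subset -> validation CI map.
    """
    import pandas as pd

    def _cohort(s):
        rng = np.random.default_rng(s)
        n = 150
        z = rng.standard_normal((n, 3))
        lin = 0.6 * z.sum(axis=1)
        t_event = rng.exponential(1.0 / (0.05 * np.exp(lin)))
        t_cens = rng.uniform(0, np.quantile(t_event, 0.9) * 2, n)
        idx = [f"P{i}" for i in range(n)]
        comp = pd.DataFrame(
            z, columns=["clinical", "gene", "radiomic"], index=idx
        )
        clin = pd.DataFrame(
            {
                "os_time": np.minimum(t_event, t_cens),
                "os_event": (t_event <= t_cens).astype(int),
            },
            index=idx,
        )
        return comp, clin

    ct, clt = _cohort(2 * seed)
    cv, clv = _cohort(2 * seed + 1)
    return signatures.combine_signatures(ct, clt, cv, clv)
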