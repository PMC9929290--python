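"""End-to-end workflow: correlation scan -> annotated PRS -> combination.

Thin orchestration over the library modules, used by the CLI and the
evaluation scripts. The target population's score is a linear combination
of K population-specific posterior-effect scores; the non-target
populations' effects are shrunk less inside regions with positive
cross-population local genetic correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import combine as combine_mod
from . import scan as scan_mod
from .gibbs import (AnnotationMap, GibbsConfig, PosteriorEffects,
                    fit_posterior_effects, make_shrinkage_plan)
from .io import HarmonizedStudySet, block_ld_set


@dataclass
class PipelineResult:
    regions: dict
    annotation: AnnotationMap
    effects: PosteriorEffects
    weights: combine_mod.MixWeights
    h2: np.ndarray
    theta: float = 0.5
    extras: dict = field(default_factory=dict)


def scan_regions(
    set_: HarmonizedStudySet,
    h2,
    scan_config: scan_mod.ScanConfig,
    target: int = 0,
    ld: list | None = None,
    top_s: int = 1000,
    annotation_p_stop: float = 0.5,
) -> tuple[dict, AnnotationMap, scan_mod.ZCovModel]:
    """Pairwise (target, k) correlation scans and the top-s annotation.

    The peel continues past the FDR cut (to ``annotation_p_stop``) so the
    annotation can use the full top-s ranking; regions carry a
    ``significant`` flag for reporting.
    """
    if ld is None:
        ld = [block_ld_set(set_, k) for k in range(set_.k)]
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(h2, float)), (set_.k,))
    model = scan_mod.build_z_covariance(set_, h2, ld=ld)
    per_pair = {}
    for k in range(set_.k):
        if k == target:
            continue
        null = scan_mod.simulate_null_qmax(model, scan_config, pops=(target, k))
        regions = scan_mod.detect_regions(set_, model, null, scan_config,
                                          pops=(target, k),
                                          p_stop=annotation_p_stop)
        per_pair[k] = scan_mod.merge_regions(
            regions, scan_config.merge_bp, set_, model,
            theta=scan_config.theta, pops=(target, k),
        )
    annotation = scan_mod.build_annotation(per_pair, s=top_s,
                                           snp_map=set_.snps)
    return per_pair, annotation, model


def run_pipeline(
    set_: HarmonizedStudySet,
    h2,
    target: int = 0,
    scan_config: scan_mod.ScanConfig | None = None,
    gibbs_config: GibbsConfig | None = None,
    panels3=None,
    p_folds: int = 4,
    annotate: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Full workflow on a harmonized study set.

    ``panels3`` are three disjoint target-population reference panels for the
    combination stage (defaults to a 3-way split of the target panel).
    ``annotate=False`` skips the scan and runs the unannotated (lambda = 1)
    model — the ablation baseline.
    """
    from .io import split_panel

    scan_config = scan_config or scan_mod.ScanConfig(seed=seed)
    gibbs_config = gibbs_config or GibbsConfig(seed=seed)
    ld = [block_ld_set(set_, k) for k in range(set_.k)]
    if annotate:
        per_pair, annotation, _model = scan_regions(
            set_, h2, scan_config, target=target, ld=ld)
        plan = make_shrinkage_plan(target, annotation, set_.k)
    else:
        per_pair = {}
        annotation = AnnotationMap(m=set_.m, omega_sets={})
        plan = make_shrinkage_plan(target, None, set_.k, m=set_.m)
    effects = fit_posterior_effects(set_, plan, gibbs_config, ld=ld)
    if panels3 is None:
        panels3 = split_panel(set_.panels[target], 3, seed=seed)
    weights = combine_mod.repeated_learning(
        set_, target, plan, panels3, p_folds=p_folds,
        config=gibbs_config, seed=seed,
    )
    return PipelineResult(
        regions=per_pair, annotation=annotation, effects=effects,
        weights=weights, h2=np.broadcast_to(np.atleast_1d(h2), (set_.k,)),
        theta=scan_config.theta,
    )


def score_cohort(result: PipelineResult, genotypes, snp_map=None):
    """Combined polygenic score for a cohort given a pipeline result."""
    return combine_mod.score_and_combine(
        result.effects, result.weights, genotypes, snp_map=snp_map,
    )
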