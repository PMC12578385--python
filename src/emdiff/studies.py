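"""Canned simulation studies used by the examples and the validation script.

These configs pin the study conditions under which the package's statistical
claims are demonstrated: a null study (type-I control of the joint DEG gate), a
power study (homogeneous x2 shifts vs 30%/x3 subpopulation shifts at 200
cells/group), a planted-geometry study for population-distance recovery, and a
demo dataset spanning genotype x age x treatment groups.

The baseline regime — NB mean ~ LogNormal(ln 5, 0.4), dispersion 10 — models
moderately expressed genes with the mild overdispersion typical of UMI counts.
"""

from __future__ import annotations

import numpy as np

from .simulate import EffectSpec, SimConfig


def power_study_config(seed: int, n_genes: int = 2000,
                       cells_per_group: int = 200,
                       n_shift: int = 40, n_subpop: int = 40,
                       shift_magnitude: float = 2.0,
                       subpop_magnitude: float = 3.0,
                       subpop_fraction: float = 0.3) -> SimConfig:
    """Two-group study with planted homogeneous and subpopulation shifts."""
    effects = [
        EffectSpec(gene=g, cell_type="neuron", group="MUT",
                   kind="shift", magnitude=shift_magnitude)
        for g in range(n_shift)
    ] + [
        EffectSpec(gene=g, cell_type="neuron", group="MUT",
                   kind="subpop_shift", magnitude=subpop_magnitude,
                   affected_fraction=subpop_fraction)
        for g in range(n_shift, n_shift + n_subpop)
    ]
    return SimConfig(
        n_genes=n_genes, n_mito_genes=13,
        cell_types=("neuron",), groups=("WT", "MUT"),
        cells_per_population=cells_per_group,
        baseline_logmean_mu=float(np.log(5.0)), baseline_logmean_sigma=0.4,
        nb_dispersion=10.0, mito_fraction_mean=0.02,
        effects=tuple(effects), seed=seed,
    )


def null_study_config(seed: int, n_genes: int = 2000,
                      cells_per_group: int = 200) -> SimConfig:
    """Same baseline regime with no planted effects (exchangeable groups)."""
    return power_study_config(seed, n_genes=n_genes,
                              cells_per_group=cells_per_group,
                              n_shift=0, n_subpop=0)


def geometry_study_config(seed: int, n_genes: int = 300,
                          cells_per_group: int = 100,
                          n_effect_genes: int = 30) -> SimConfig:
    """Three groups where the treated late stage sits nearer the early stage.

    The same genes are shifted x3 in the untreated late group but only x1.5 in
    the treated late group, so in expression space the treated-late centroid
    lies between early and untreated-late, closer to early.
    """
    effects = []
    for g in range(n_effect_genes):
        effects.append(EffectSpec(gene=g, cell_type="neuron", group="late",
                                  kind="shift", magnitude=3.0))
        effects.append(EffectSpec(gene=g, cell_type="neuron", group="late_aso",
                                  kind="shift", magnitude=1.5))
    return SimConfig(
        n_genes=n_genes, n_mito_genes=6,
        cell_types=("neuron",), groups=("early", "late", "late_aso"),
        cells_per_population=cells_per_group,
        baseline_logmean_mu=float(np.log(5.0)), baseline_logmean_sigma=0.4,
        nb_dispersion=10.0, effects=tuple(effects), seed=seed,
    )


def demo_pipeline_config(out_dir: str, seed: int = 0):
    """Full-pipeline demo: 3 cell types x 5 groups (genotype x age x treatment)
    x 200 cells, 1000 genes, with age-graded planted shifts where the treated
    late-stage mutant is intermediate between early and untreated late."""
    from .pipeline import PipelineConfig

    groups = ["WT_26", "MUT_26", "WT_52", "MUT_52", "MUT_52_ASO"]
    cell_types = ["neuron", "astrocyte", "oligo"]
    effects = []
    for ct in cell_types:
        for g in range(10):
            effects.append({"gene": g, "cell_type": ct, "group": "MUT_26",
                            "kind": "shift", "magnitude": 2.0})
            effects.append({"gene": g, "cell_type": ct, "group": "MUT_52",
                            "kind": "shift", "magnitude": 4.0})
            effects.append({"gene": g, "cell_type": ct, "group": "MUT_52_ASO",
                            "kind": "shift", "magnitude": 2.5})
        for g in range(10, 16):
            effects.append({"gene": g, "cell_type": ct, "group": "MUT_26",
                            "kind": "subpop_shift", "magnitude": 3.0,
                            "affected_fraction": 0.3})
    return PipelineConfig(
        out_dir=out_dir,
        simulate={
            "n_genes": 1000, "n_mito_genes": 13,
            "cell_types": cell_types, "groups": groups,
            "cells_per_population": 200,
            "baseline_logmean_mu": float(np.log(5.0)),
            "baseline_logmean_sigma": 0.4,
            "nb_dispersion": 10.0,
            "effects": effects,
        },
        contrasts=[
            {"group_ref": "WT_26", "group_alt": "MUT_26"},
            {"group_ref": "WT_52", "group_alt": "MUT_52"},
        ],
        n_pcs=30, distance_pcs=30,
        seed=seed,
    )
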