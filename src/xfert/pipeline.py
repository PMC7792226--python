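"""End-to-end orchestration on a synthetic population: simulate, QC, GWAS,
dosage derivation, breeding-value effects and the economic index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dosage as dosage_mod
from . import effects as effects_mod
from . import geno_qc, gwas, landrace, simdata


@dataclass
class GwasResult:
    population: simdata.Population
    labels: simdata.CaseControlLabels
    genotypes: geno_qc.GenotypeMatrix
    qc_report: geno_qc.QcReport
    grm: gwas.Grm
    variance: gwas.VarianceComponents
    records: list
    summary: gwas.GwasSummary


def run_gwas(config: simdata.SimConfig, alpha: float = 0.05,
             lambda_method: str = "regression") -> GwasResult:
    """Simulate a population and run the full case-control mixed-model scan."""
    pop = simdata.simulate_population(config)
    labels = simdata.simulate_case_labels(pop, config)
    gm = simdata.genotype_matrix(pop, labels.sample_ids)
    gm_qc, report = geno_qc.qc_filter(gm)
    grm = gwas.compute_grm(gm_qc)
    vc = gwas.reml_fit(labels.status, grm)
    records = gwas.mlma_scan(gm_qc, labels.status, grm, vc)
    summary = gwas.summarize(records, alpha=alpha,
                             lambda_method=lambda_method)
    return GwasResult(pop, labels, gm_qc, report, grm, vc, records, summary)


@dataclass
class EffectsResult:
    freqs: dosage_mod.PopFreqs
    assignments: list
    groups: pd.DataFrame
    estimates: list
    index: float


def run_effects(pop: simdata.Population, config: simdata.SimConfig,
                ebvs: pd.DataFrame | None = None) -> EffectsResult:
    """Dosage derivation and trait-effect estimation on the simulated herd.

    Parents that exist in the pedigree are treated as genotyped; founder
    parents are unknown, so the frequency-based dosage cells are exercised
    too.  Sows themselves are treated as ungenotyped (the derivation path).
    """
    if ebvs is None:
        ebvs = simdata.simulate_ebvs(pop, config)
    dose = pop.causal_dose()

    sows = np.flatnonzero((pop.sex == "F") & pop.fertility_status)
    sow_ids = set(pop.ids[sows])
    ped = pop.pedigree_frame()
    ped = ped[ped["id"].isin(sow_ids)]

    parent_genotypes: dict[str, str] = {}
    n_boar = [0, 0]            # C, T
    n_sow = [0, 0]             # C/C, C/T
    for col in ("sire", "dam"):
        for parent in ped[col].unique():
            if parent == "0" or parent in parent_genotypes:
                continue
            i = int(pop.index_of([parent])[0])
            if pop.sex[i] == "M":
                g = "T" if dose[i] else "C"
                n_boar[dose[i]] += 1
            else:
                g = "C/T" if dose[i] == 1 else "C/C"
                n_sow[min(dose[i], 1)] += 1
            parent_genotypes[parent] = g
    freqs = dosage_mod.estimate_parent_freqs(n_boar[0], n_boar[1],
                                             n_sow[0], n_sow[1])
    assignments = dosage_mod.assign_dosages(ped, parent_genotypes, freqs)
    groups = dosage_mod.dosage_groups(assignments)
    dosages = {a.sow_id: a.dosage for a in assignments}
    estimates = effects_mod.multi_trait_effects(ebvs, dosages)
    index = effects_mod.economic_index(estimates,
                                       landrace.ECONOMIC_WEIGHTS)
    return EffectsResult(freqs, assignments, groups, estimates, index)
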