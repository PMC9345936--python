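"""End-to-end inference chain: plasma table -> patient phenotypes.

Chains the package's stages in study order: imputation and fold changes
on the plasma table, baseline transport quartiles from flux sampling,
fold-change constraining with feasibility relaxation per patient,
activity evaluation, constant-activity filtering, complete-linkage
clustering and PLS-DA VIP ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activities as act_mod
from . import constrain as con_mod
from . import metabolomics as met_mod
from . import netcore, phenotyping, synthdata

__all__ = [
    "PipelineResult",
    "patient_fold_changes",
    "baseline_quartiles",
    "build_cohort_models",
    "run_pipeline",
]


def patient_fold_changes(
    table: met_mod.MetaboliteTable,
    by_phenotype: pd.Series | None = None,
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-patient (default) or per-phenotype fold changes vs control means.

    Per-patient: row = patient concentrations / control-group mean.
    With ``by_phenotype`` (patient id -> phenotype), every patient in a
    phenotype shares that phenotype's mean fold change instead.
    """
    ctl_mean = table.subset(control_group).mean(axis=0)
    if (ctl_mean <= 0).any():
        raise ValueError("control mean <= 0: fold changes undefined")
    patients = table.values.loc[(table.group != control_group).to_numpy()]
    fc = patients / ctl_mean
    if by_phenotype is None:
        return fc
    by_phenotype = pd.Series(by_phenotype).loc[fc.index]
    return fc.groupby(by_phenotype).transform("mean")


def baseline_quartiles(
    net: netcore.MetabolicNetwork,
    n_samples: int = 1000,
    seed: int = 0,
    burn_in: int = 1000,
    thinning: int = 10,
    transport_ids: list[str] | None = None,
) -> netcore.TransportQuartiles:
    """Transport-flux quartiles of the baseline network by hit-and-run.

    ``transport_ids`` restricts the quartile summary (e.g. to the
    measured-metabolite transports); default is every transport.  Waste
    sinks such as CO2/NH4 secretion should normally be excluded from
    constraining: their marginal quartile box reflects total baseline
    turnover and would cap every patient's catabolism at baseline levels
    regardless of the measured fold changes.
    """
    sample = netcore.sample_fluxes(
        net, n=n_samples, seed=seed, burn_in=burn_in, thinning=thinning
    )
    return netcore.transport_quartiles(
        sample, list(transport_ids) if transport_ids is not None else net.transport_ids
    )


def build_cohort_models(
    net: netcore.MetabolicNetwork,
    quartiles: netcore.TransportQuartiles,
    fc: pd.DataFrame,
    mapping: pd.DataFrame,
    fc_provenance: str = "per-patient",
) -> list[con_mod.PatientModel]:
    """One relaxed, fold-change-constrained model per fold-change row."""
    import warnings

    models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unmapped-metabolite warnings, once per run
        for subject, row in fc.iterrows():
            rxn_fc = con_mod.map_metabolites(row, mapping, net)
            bounds = con_mod.build_patient_bounds(quartiles, rxn_fc)
            models.append(
                con_mod.relax_to_feasible(
                    net, bounds, subject_id=str(subject),
                    fc_provenance=fc_provenance,
                )
            )
    return models


@dataclass
class PipelineResult:
    table: met_mod.MetaboliteTable
    truth: synthdata.SyntheticTruth | None
    models: list
    matrix: pd.DataFrame  # raw activity matrix
    filtered: pd.DataFrame  # after constant-activity removal
    removed: pd.DataFrame  # constant activities and their values
    assignment: phenotyping.PhenotypeAssignment
    vip: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    cfg: synthdata.CohortConfig | None = None,
    *,
    net: netcore.MetabolicNetwork | None = None,
    quartiles: netcore.TransportQuartiles | None = None,
    table: met_mod.MetaboliteTable | None = None,
    truth: synthdata.SyntheticTruth | None = None,
    catalogue=None,
    mapping: pd.DataFrame | None = None,
    k: int = 4,
    impute_method: str = "median",
    n_samples: int = 1000,
    sampling_seed: int = 0,
) -> PipelineResult:
    """Run the full chain on a synthetic (or supplied) cohort.

    ``quartiles`` can be passed in to amortise the baseline sampling
    over repeated runs; they depend only on the network and the
    sampling seed, not on the cohort.
    """
    net = net or synthdata.make_toy_network()
    catalogue = catalogue or synthdata.toy_activity_catalogue()
    mapping = mapping if mapping is not None else synthdata.toy_transport_mapping()
    if table is None:
        table, truth = synthdata.simulate_cohort(cfg or synthdata.CohortConfig())
    if quartiles is None:
        measured = sorted(set(mapping["reaction_id"]))
        quartiles = baseline_quartiles(
            net, n_samples=n_samples, seed=sampling_seed, transport_ids=measured
        )
    table = met_mod.impute_missing(table, method=impute_method, seed=sampling_seed)
    fc = patient_fold_changes(table)
    models = build_cohort_models(net, quartiles, fc, mapping)
    matrix = act_mod.evaluate_matrix(models, catalogue)
    filtered, removed = act_mod.filter_constant(matrix)
    assignment = phenotyping.cluster_patients(filtered, k=k, scale="zscore")
    sd = filtered.std(axis=0, ddof=1).replace(0.0, 1.0)
    zscored = (filtered - filtered.mean(axis=0)) / sd
    vip = phenotyping.plsda_vip(zscored, assignment.labels, n_components=2)
    extras: dict = {}
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        extras["ari"] = float(
            adjusted_rand_score(
                truth.labels.loc[filtered.index], assignment.labels
            )
        )
    return PipelineResult(
        table=table,
        truth=truth,
        models=models,
        matrix=matrix,
        filtered=filtered,
        removed=removed,
        assignment=assignment,
        vip=vip,
        extras=extras,
    )
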