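"""Synthetic study materials: toy EC network, catalogue, and plasma cohorts.

No metabolomics data are deposited for the study design this package
targets, and the full genome-scale endothelial model is external, so
every pipeline stage is exercised on (a) a small, mass-balanced
endothelial-flavoured network exposing lumped glycolysis, TCA +
oxidative phosphorylation, malonyl-CoA synthesis, beta-oxidation and one
degradation pathway per amino acid, and (b) synthetic plasma cohorts
that emulate the study design: 35 patients in four planted metabolic
phenotypes (glycolytic B; oxidative, high-amino-acid-catabolism C and D;
intermediate/beta-oxidation A) plus 20 healthy controls over a
51-metabolite panel with <1% missing values.

All quantities are synthetic: effect sizes are free parameters of the
generator, never estimates of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolomics import MetaboliteTable
from .netcore import DEFAULT_BOUND, MetabolicNetwork

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "make_toy_network",
    "toy_activity_catalogue",
    "toy_transport_mapping",
    "simulate_cohort",
    "inject_missing",
    "AMINO_ACIDS",
    "PANEL",
]

# the 19 amino acids whose degradation pathways the phenotypes separate on
# (ornithine is one of the 19)
AMINO_ACIDS: dict[str, tuple[int, int]] = {  # name -> (carbons, nitrogens)
    "alanine": (3, 1),
    "glycine": (2, 1),
    "serine": (3, 1),
    "histidine": (6, 3),
    "asparagine": (4, 2),
    "phenylalanine": (9, 1),
    "valine": (5, 1),
    "proline": (5, 1),
    "tyrosine": (9, 1),
    "aspartate": (4, 1),
    "threonine": (4, 1),
    "isoleucine": (6, 1),
    "tryptophan": (11, 2),
    "glutamate": (5, 1),
    "glutamine": (5, 2),
    "cysteine": (3, 1),
    "ornithine": (5, 2),
    "leucine": (6, 1),
    "lysine": (6, 2),
}

CORE_PANEL = [
    "glucose",
    "lactate",
    "pyruvate",
    "glycerol",
    "3-hydroxybutyrate",
    "citrate",
    "succinate",
    "malate",
    "palmitate",
]

# inert panel members: quantified in plasma but not wired into the toy
# network beyond their exchange, padding the panel to 51 metabolites
INERT_PANEL = [
    "methionine",
    "arginine",
    "taurine",
    "carnitine",
    "choline",
    "betaine",
    "creatinine",
    "creatine",
    "urate",
    "hypoxanthine",
    "inosine",
    "uridine",
    "cytidine",
    "sarcosine",
    "citrulline",
    "kynurenine",
    "serotonin",
    "acetoacetate",
    "glycerate",
    "erythritol",
    "myo-inositol",
    "hippurate",
    "indoxyl-sulfate",
]

PANEL: list[str] = CORE_PANEL + list(AMINO_ACIDS) + INERT_PANEL
assert len(PANEL) == 51

_BASELINES = {
    "glucose": 5000.0, "lactate": 1500.0, "pyruvate": 60.0, "glycerol": 80.0,
    "3-hydroxybutyrate": 100.0, "citrate": 120.0, "succinate": 8.0,
    "malate": 10.0, "palmitate": 100.0,
    "alanine": 400.0, "glycine": 250.0, "serine": 120.0, "histidine": 80.0,
    "asparagine": 50.0, "phenylalanine": 60.0, "valine": 230.0,
    "proline": 180.0, "tyrosine": 65.0, "aspartate": 8.0, "threonine": 140.0,
    "isoleucine": 65.0, "tryptophan": 55.0, "glutamate": 60.0,
    "glutamine": 600.0, "cysteine": 250.0, "ornithine": 60.0,
    "leucine": 130.0, "lysine": 180.0,
}
for _i, _m in enumerate(INERT_PANEL):
    _BASELINES[_m] = 30.0 + 5.0 * _i  # arbitrary but fixed inert baselines


def _ex(met: str) -> str:
    return f"EX_{met}"


def make_toy_network() -> MetabolicNetwork:
    """Deterministic ~90-reaction endothelial-flavoured toy network.

    Lumped stoichiometry (cofactors carry no formula; carbon/nitrogen
    balance holds for every internal multi-metabolite reaction):

    * glycolysis: glucose -> 2 pyruvate + 2 ATP + 2 NADH(cyt)
    * lactate branch: pyruvate + NADH(cyt) -> lactate
    * shuttle: NADH(cyt) -> NADH(mit)
    * PDH: pyruvate -> acetyl-CoA + NADH(mit) + CO2
    * TCA: acetyl-CoA -> 4 NADH(mit) + 2 CO2
    * oxidative phosphorylation: NADH(mit) -> 2.5 ATP
      (so one glucose yields 2 glycolytic + 30 oxidative = 32 ATP)
    * beta-oxidation: palmitate + ATP -> 8 acetyl-CoA + 14 NADH(mit)
    * malonyl-CoA synthesis: acetyl-CoA + CO2 + ATP -> malonyl-CoA
    * one lumped degradation per amino acid:
      aa -> acetyl-CoA + (C-2) CO2 + N NH4 + 2 NADH(mit)
    * an isomerase pair (citrate <-> isocitrate) forming an internal
      loop whose cycle capacity always saturates at 1000, and a
      dead-end serine phosphorylation that is always blocked — the two
      uninformative extremes the constant-activity filter removes.

    Exchange reactions exist for every panel metabolite (negative flux =
    uptake); nutrient uptakes are capped at physiological-toy magnitudes
    so baseline flux sampling gives informative transport quartiles.
    """
    mets: list[str] = []
    formulas: dict[str, str] = {}

    def add_met(mid: str, formula: str | None = None) -> None:
        mets.append(mid)
        if formula:
            formulas[mid] = formula

    for m in PANEL:
        add_met(m)
    formulas.update(
        {
            "glucose": "C6", "lactate": "C3", "pyruvate": "C3",
            "glycerol": "C3", "3-hydroxybutyrate": "C4", "citrate": "C6",
            "succinate": "C4", "malate": "C4", "palmitate": "C16",
        }
    )
    for aa, (c, n) in AMINO_ACIDS.items():
        formulas[aa] = f"C{c}N{n}"
    add_met("atp")
    add_met("nadh")
    add_met("nadh_m")
    add_met("accoa", "C2")
    add_met("malcoa", "C3")
    add_met("co2", "C1")
    add_met("nh4", "N1")
    add_met("isocitrate", "C6")
    add_met("phosphoserine", "C3N1")

    reactions: list[tuple[str, dict[str, float], float, float, bool, str]] = []

    def rxn(rid, stoich, lb, ub, transport=False, subsystem=""):
        reactions.append((rid, stoich, lb, ub, transport, subsystem))

    # uptake caps kept at physiological-toy magnitudes so the summed ATP
    # capacity of a patient model stays below the 1000 saturation bound
    uptake = {
        "glucose": (-5.0, 0.0),
        "lactate": (0.0, 20.0),
        "pyruvate": (-1.0, 1.0),
        "glycerol": (-1.0, 0.0),
        "3-hydroxybutyrate": (-1.0, 0.0),
        "citrate": (-1.0, 0.0),
        "succinate": (-1.0, 0.0),
        "malate": (-1.0, 0.0),
        "palmitate": (-1.0, 0.0),
    }
    for m in PANEL:
        if m in uptake:
            lo, up = uptake[m]
        elif m in AMINO_ACIDS:
            lo, up = -1.0, 0.0
        else:  # inert panel member: exchange only, stoichiometrically blocked
            lo, up = -1.0, 1.0
        rxn(_ex(m), {m: -1.0}, lo, up, transport=True, subsystem="exchange")
    rxn(_ex("co2"), {"co2": -1.0}, 0.0, DEFAULT_BOUND, True, "exchange")
    rxn(_ex("nh4"), {"nh4": -1.0}, 0.0, DEFAULT_BOUND, True, "exchange")

    rxn("GLYC", {"glucose": -1, "pyruvate": 2, "atp": 2, "nadh": 2},
        0, DEFAULT_BOUND, subsystem="glycolysis")
    rxn("LDH", {"pyruvate": -1, "nadh": -1, "lactate": 1},
        0, DEFAULT_BOUND, subsystem="glycolysis")
    rxn("NSHUT", {"nadh": -1, "nadh_m": 1}, 0, DEFAULT_BOUND, subsystem="shuttle")
    rxn("PDH", {"pyruvate": -1, "accoa": 1, "nadh_m": 1, "co2": 1},
        0, DEFAULT_BOUND, subsystem="tca")
    rxn("TCA", {"accoa": -1, "nadh_m": 4, "co2": 2},
        0, DEFAULT_BOUND, subsystem="tca")
    rxn("OXPHOS", {"nadh_m": -1, "atp": 2.5}, 0, DEFAULT_BOUND, subsystem="oxphos")
    # uncoupled mitochondrial NADH oxidation (heat/ROS dissipation); keeps
    # models with forced catabolic uptakes feasible when OXPHOS is knocked out
    rxn("NADH_M_DISS", {"nadh_m": -1}, 0, DEFAULT_BOUND, subsystem="oxphos")
    rxn("ATPM", {"atp": -1}, 0, DEFAULT_BOUND, subsystem="demand")
    rxn("GLYCEROL_DEG", {"glycerol": -1, "pyruvate": 1, "nadh": 1},
        0, DEFAULT_BOUND, subsystem="glycolysis")
    rxn("BHB_DEG", {"3-hydroxybutyrate": -1, "accoa": 2, "nadh_m": 1},
        0, DEFAULT_BOUND, subsystem="ketone")
    rxn("CITLY", {"citrate": -1, "atp": -1, "accoa": 1, "malate": 1},
        0, DEFAULT_BOUND, subsystem="lipid")
    rxn("SUCC_DEG", {"succinate": -1, "malate": 1, "nadh_m": 1},
        0, DEFAULT_BOUND, subsystem="tca")
    rxn("MAL_DEG", {"malate": -1, "pyruvate": 1, "co2": 1, "nadh_m": 1},
        0, DEFAULT_BOUND, subsystem="tca")
    rxn("BETAOX", {"palmitate": -1, "atp": -1, "accoa": 8, "nadh_m": 14},
        0, DEFAULT_BOUND, subsystem="lipid")
    rxn("MALCOA_SYN", {"accoa": -1, "co2": -1, "atp": -1, "malcoa": 1},
        0, DEFAULT_BOUND, subsystem="lipid")
    rxn("DM_malcoa", {"malcoa": -1}, 0, DEFAULT_BOUND, subsystem="demand")
    rxn("ACO_F", {"citrate": -1, "isocitrate": 1}, 0, DEFAULT_BOUND, subsystem="tca")
    rxn("ACO_B", {"isocitrate": -1, "citrate": 1}, 0, DEFAULT_BOUND, subsystem="tca")
    rxn("SER_PHOS", {"serine": -1, "atp": -1, "phosphoserine": 1},
        0, DEFAULT_BOUND, subsystem="dead-end")
    for aa, (c, n) in AMINO_ACIDS.items():
        stoich = {aa: -1.0, "accoa": 1.0, "nh4": float(n), "nadh_m": 2.0}
        if c - 2:
            stoich["co2"] = float(c - 2)
        rxn(f"AADEG_{aa}", stoich, 0, DEFAULT_BOUND,
            subsystem="amino_acid_degradation")

    met_pos = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(reactions)))
    lb = np.empty(len(reactions))
    ub = np.empty(len(reactions))
    rxn_ids, transport_ids, subsystems = [], [], {}
    for j, (rid, stoich, lo, up, is_t, sub) in enumerate(reactions):
        rxn_ids.append(rid)
        lb[j], ub[j] = lo, up
        for m, coef in stoich.items():
            S[met_pos[m], j] = coef
        if is_t:
            transport_ids.append(rid)
        if sub:
            subsystems[rid] = sub
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        transport_ids=transport_ids,
        formulas=formulas,
        subsystems=subsystems,
        objective="ATPM",
    )


def toy_activity_catalogue():
    """Activity catalogue matching :func:`make_toy_network` (26 activities)."""
    from .activities import ActivityDefinition

    catalogue = [
        ActivityDefinition("atp_overall", "ATPM", "max", (), "energy"),
        ActivityDefinition("atp_glycolysis", "ATPM", "max", ("OXPHOS",), "energy"),
        ActivityDefinition("nadh_tca", "TCA", "max", (), "tca"),
        ActivityDefinition("malonyl_coa_synthesis", "MALCOA_SYN", "max", (), "lipid"),
        ActivityDefinition("beta_oxidation", "BETAOX", "max", (), "lipid"),
        ActivityDefinition("aconitase_cycle", "ACO_F", "max", (), "tca"),
        ActivityDefinition("serine_phosphorylation", "SER_PHOS", "max", (), "dead-end"),
    ]
    for aa in AMINO_ACIDS:
        catalogue.append(
            ActivityDefinition(
                f"degradation_{aa}", f"AADEG_{aa}", "max", (),
                "amino_acid_degradation",
            )
        )
    return catalogue


def toy_transport_mapping() -> pd.DataFrame:
    """Metabolite -> transport-reaction mapping for the toy network (1:1)."""
    return pd.DataFrame(
        {"metabolite_id": PANEL, "reaction_id": [_ex(m) for m in PANEL]}
    )


# ----------------------------------------------------------------------
# Cohort simulation
# ----------------------------------------------------------------------

def _default_effects() -> dict[str, dict[str, float]]:
    """Planted per-metabolite fold effects on control means, per phenotype.

    A: intermediate, beta-oxidation-consistent (lipid fuels up, amino
       acids mildly down).  B: glycolytic (glucose/lactate up).  C:
       oxidative with high amino-acid catabolism except ornithine/lysine,
       lipogenic precursor (citrate) low.  D: strongest amino-acid
       catabolism across all 19.
    """
    aa = list(AMINO_ACIDS)
    eff: dict[str, dict[str, float]] = {
        "A": {"palmitate": 1.6, "3-hydroxybutyrate": 1.5, "glycerol": 1.3,
              "lactate": 1.1, "citrate": 0.9},
        "B": {"glucose": 2.0, "lactate": 1.7, "pyruvate": 1.4,
              "palmitate": 0.9, "3-hydroxybutyrate": 0.9, "citrate": 1.2},
        "C": {"glucose": 0.65, "lactate": 0.7, "palmitate": 1.8,
              "3-hydroxybutyrate": 1.5, "citrate": 0.5, "succinate": 1.5,
              "malate": 1.5},
        "D": {"glucose": 0.9, "lactate": 0.9, "palmitate": 1.2, "citrate": 0.8},
    }
    for m in aa:
        eff["A"][m] = 0.55
        eff["B"][m] = 1.1
        eff["C"][m] = 1.1 if m in ("ornithine", "lysine") else 1.7
        eff["D"][m] = 2.2
    return eff


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort generator."""

    n_per_phenotype: dict[str, int] = field(
        default_factory=lambda: {"A": 13, "B": 15, "C": 3, "D": 4}
    )
    n_controls: int = 20
    panel: list[str] = field(default_factory=lambda: list(PANEL))
    effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    noise_sd: float = 0.20  # lognormal sd on the natural-log scale
    missing_rate: float = 0.01
    seed: int = 0
    diagnoses: dict[str, int] = field(
        default_factory=lambda: {"IPAH": 12, "CTD-aPAH": 12, "CTEPH": 11}
    )

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_phenotype.values()) or self.n_controls < 0:
            raise ValueError("subject counts must be >= 0")
        if not 0 <= self.missing_rate < 0.1:
            raise ValueError("missing_rate must be in [0, 0.1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        panel = set(self.panel)
        for ph, eff in self.effects.items():
            extra = set(eff) - panel
            if extra:
                raise ValueError(
                    f"effect template {ph} references non-panel metabolites: "
                    f"{sorted(extra)}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: planted labels and expected means."""

    labels: pd.Series  # patient id -> planted phenotype
    expected: pd.DataFrame  # subjects x metabolites expected concentration


def simulate_cohort(cfg: CohortConfig | None = None) -> tuple[MetaboliteTable, SyntheticTruth]:
    """Draw a plasma cohort around planted phenotype effect templates.

    Controls are lognormal around the panel baselines; each patient is
    lognormal around baseline x phenotype effect.  The multiplicative
    noise is mean-one (``exp(sd*z - sd^2/2)``) so group means converge to
    the template means.  Seed-deterministic.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    baselines = np.array([_BASELINES[m] for m in cfg.panel])

    phenotypes = [
        ph for ph, n in sorted(cfg.n_per_phenotype.items()) for _ in range(n)
    ]
    rng.shuffle(phenotypes)
    n_pat = len(phenotypes)
    patient_ids = [f"P{i + 1:02d}" for i in range(n_pat)]
    control_ids = [f"H{i + 1:02d}" for i in range(cfg.n_controls)]

    def draw_noise() -> np.ndarray:
        # mean-one multiplicative lognormal noise; tails truncated at 2.5 sd,
        # emulating the outlier exclusion of a QC'd targeted panel
        z = np.clip(rng.standard_normal(len(cfg.panel)), -2.5, 2.5)
        return np.exp(cfg.noise_sd * z - cfg.noise_sd**2 / 2.0)

    rows, expected_rows = [], []
    for ph in phenotypes:
        eff = np.array([cfg.effects.get(ph, {}).get(m, 1.0) for m in cfg.panel])
        mean = baselines * eff
        rows.append(mean * draw_noise())
        expected_rows.append(mean)
    for _ in range(cfg.n_controls):
        rows.append(baselines * draw_noise())
        expected_rows.append(baselines)

    index = pd.Index(patient_ids + control_ids, name="sample_id")
    values = pd.DataFrame(rows, index=index, columns=cfg.panel)
    group = pd.Series(
        ["patient"] * n_pat + ["control"] * cfg.n_controls, index=index, name="group"
    )
    diag_pool = [d for d, n in sorted(cfg.diagnoses.items()) for _ in range(n)]
    if len(diag_pool) < n_pat:
        diag_pool += ["unspecified"] * (n_pat - len(diag_pool))
    rng.shuffle(diag_pool)
    diagnosis = pd.Series(
        diag_pool[:n_pat] + ["control"] * cfg.n_controls, index=index,
        name="diagnosis",
    )
    table = MetaboliteTable(values=values, group=group, diagnosis=diagnosis)
    truth = SyntheticTruth(
        labels=pd.Series(phenotypes, index=patient_ids, name="phenotype"),
        expected=pd.DataFrame(expected_rows, index=index, columns=cfg.panel),
    )
    if cfg.missing_rate > 0:
        table = inject_missing(table, cfg.missing_rate, seed=cfg.seed + 1)
    return table, truth


def inject_missing(
    table: MetaboliteTable, rate: float, seed: int
) -> MetaboliteTable:
    """Punch MCAR holes into the table with expected fraction ``rate``."""
    if not 0 <= rate < 0.1:
        raise ValueError("rate must be in [0, 0.1)")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    mask = rng.random(table.values.shape) < rate
    # keep >= 2 observed values per column so imputation stays defined
    for j in range(mask.shape[1]):
        observed = (~mask[:, j]).sum()
        if observed < 2:
            keep = rng.choice(mask.shape[0], size=2, replace=False)
            mask[keep, j] = False
    values = table.values.mask(pd.DataFrame(
        mask, index=table.values.index, columns=table.values.columns
    ))
    out = object.__new__(MetaboliteTable)
    out.values = values
    out.group = table.group
    out.diagnosis = table.diagnosis
    out.missing_threshold = table.missing_threshold
    return out
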