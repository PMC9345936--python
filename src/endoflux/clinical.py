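"""Clinical table summaries for the metabolic phenotypes.

NT-proBNP, the plasma marker of cardiac strain used as the
disease-severity readout, is expressed as a percentage of the upper
reference limit (the reference maximum equals 100%).  The package ships
the published per-phenotype median severities of the 35-patient
pulmonary-hypertension cohort (phenotypes A-D) as reference data so the
phenotype severity contrasts can be recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_phenotype_reference", "median_ratio", "severity_contrasts"]


def load_phenotype_reference() -> pd.DataFrame:
    """Per-phenotype cohort sizes and NT-proBNP medians (% of ULN)."""
    with resources.files("endoflux.data").joinpath(
        "phenotype_clinical_reference.csv"
    ).open() as fh:
        return pd.read_csv(fh).set_index("phenotype")


def median_ratio(
    summary: pd.DataFrame, numerator: str, denominator: str,
    column: str = "ntprobnp_median_pct_uln",
) -> float:
    """Ratio of two phenotypes' median values from a summary table."""
    for ph in (numerator, denominator):
        if ph not in summary.index:
            raise KeyError(f"phenotype {ph!r} not in summary table")
    den = float(summary.loc[denominator, column])
    if den == 0:
        raise ValueError("denominator median is zero")
    return float(summary.loc[numerator, column]) / den


def severity_contrasts(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """The two headline severity contrasts: D vs B and C vs A.

    D and C carry the worst disease severity, B the mildest; the ratios
    of median NT-proBNP quantify the spread across metabolic phenotypes.
    """
    if summary is None:
        summary = load_phenotype_reference()
    rows = [
        {"contrast": "D/B", "ratio": median_ratio(summary, "D", "B")},
        {"contrast": "C/A", "ratio": median_ratio(summary, "C", "A")},
    ]
    out = pd.DataFrame(rows).set_index("contrast")
    out["rounded"] = out["ratio"].round().astype(int)
    return out
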