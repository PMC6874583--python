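"""Bundled reference data.

``load_clinical_cohort`` returns the published per-subject summary of a
26-subject adolescent concussion cohort assessed with the multi-deviant
oddball protocol: previous concussion count, days since injury,
post-concussion symptom scale (PCSS) and depression-inventory (CDI)
scores, and the classifier's single-trial accuracy, at the first test and
— for the 19 subjects who returned — at a follow-up test. ``SR`` marks
subjects whose symptoms had fully resolved (PCSS of 0) by the follow-up.

These numbers serve the worked examples: summary statistics of the cohort
and the mixed Recovery x Testing-Date ANOVA on the longitudinal
accuracies. They are clinical reference values, not simulator output.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_clinical_cohort() -> pd.DataFrame:
    """The 26-subject concussed-cohort summary table (percent accuracies)."""
    with resources.files("trodnet.data").joinpath("clinical_cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    df["longitudinal"] = df["longitudinal"].astype(bool)
    return df


def longitudinal_anova_table(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """The 19 returning subjects in the layout ``mixed_anova`` expects."""
    if df is None:
        df = load_clinical_cohort()
    sub = df[df["longitudinal"]].copy()
    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"].astype(str),
            "recovery": sub["symptom_resolution"],
            "accuracy_t1": sub["trial_accuracy_t1"].astype(float),
            "accuracy_t2": sub["trial_accuracy_t2"].astype(float),
        }
    ).reset_index(drop=True)
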