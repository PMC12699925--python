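"""Packaged fixture: the 17 trials whose sample-size calculations were modified.

The modification table ships as a CSV inside the package (one row per
modification: standardised target effect before and after, total-sample-size
change, reason, who induced it, and the standardised observed effect of the
trial's primary outcome).  :func:`table4_cohort` lifts it into full
:class:`~trialoptim.model.TrialRecord` objects so the whole pipeline — version
trajectories, modification impact, optimism — runs on it end to end.

The lifted records are synthetic carriers for the printed standardised
values: each protocol version is encoded as a continuous outcome with unit SD
and a raw target difference equal to the standardised effect (so direct
standardisation returns the printed value exactly), with the sample size
derived from the design parameters.  Seven trials modified during ethics
review, ten during amendments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import DesignParameters, Modification, OutcomeResult, TrialRecord
from .standardise import forward_sample_size

__all__ = ["load_table4_modifications", "table4_cohort"]

_PHASE_MAP = {"ethics": "ethics_review", "amendment": "amendment"}


def load_table4_modifications() -> pd.DataFrame:
    """The packaged modification table, one row per modification (20 rows)."""
    with resources.files("trialoptim.data").joinpath("table4_modifications.csv").open(
        "rb"
    ) as fh:
        return pd.read_csv(fh)


def table4_cohort() -> list[TrialRecord]:
    """The 17 modified trials as fully validated trial records.

    Versions carry alpha = 0.05, two-sided, power = 0.80, 1:1 allocation and
    the per-arm sizes implied by the version's standardised target; the
    result is the printed standardised observed effect on a unit-SD
    continuous scale.
    """
    df = load_table4_modifications()
    records: list[TrialRecord] = []
    for trial_id, rows in df.groupby("trial_id", sort=False):
        rows = rows.sort_values("from_version")
        phase = _PHASE_MAP[rows.iloc[0]["phase"]]
        # per-version standardised targets: the first row's "before", then
        # each row's "after" at its to_version
        es_by_version: dict[int, float] = {
            int(rows.iloc[0]["from_version"]): float(rows.iloc[0]["target_es_before"])
        }
        for _, row in rows.iterrows():
            es_by_version[int(row["to_version"])] = float(row["target_es_after"])

        versions = []
        for idx in sorted(es_by_version):
            es = es_by_version[idx]
            design = DesignParameters(
                version_index=idx,
                alpha=0.05,
                sided="two",
                power=0.80,
                allocation_ratio=1.0,
                outcome_type="continuous",
                target_difference=es,
                variability_or_control_rate=1.0,
            )
            n1, n2 = forward_sample_size(es, design)
            versions.append(
                design.model_copy(
                    update={"n_target_evaluable": n1 + n2, "n_target_total": n1 + n2}
                )
            )
        modifications = [
            Modification(
                phase=phase,
                from_version=int(row["from_version"]),
                to_version=int(row["to_version"]),
                reason=str(row["reason"]),
                induced_by=str(row["induced_by"]),
                sample_size_change_fraction=float(row["total_n_change_fraction"]),
            )
            for _, row in rows.iterrows()
        ]
        final = versions[-1]
        n_total = final.n_target_evaluable or 2
        n1 = n_total // 2
        result = OutcomeResult(
            effect_estimate=float(rows.iloc[0]["observed_es"]),
            sd_pooled=1.0,
            n_achieved_per_arm=(n1, n_total - n1),
            source="publication",
        )
        records.append(
            TrialRecord(
                trial_id=str(trial_id),
                versions=versions,
                modifications=modifications,
                result=result,
            )
        )
    return records
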