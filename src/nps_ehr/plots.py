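"""Matplotlib report figures: grouped prevalence bars and EHR/NPI stacks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def prevalence_bars(estimates_by_cohort: dict, out_path) -> None:
    """Grouped bar chart of adjusted prevalence per category and cohort."""
    cohorts = list(estimates_by_cohort)
    categories = sorted(
        {e.category for ests in estimates_by_cohort.values() for e in ests}
    )
    width = 0.8 / max(len(cohorts), 1)
    x = np.arange(len(categories))
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, cohort in enumerate(cohorts):
        by_cat = {e.category: e for e in estimates_by_cohort[cohort]}
        heights, errs = [], []
        for cat in categories:
            e = by_cat.get(cat)
            if e is None or not e.gate_passed:
                heights.append(0.0)
                errs.append(0.0)
            else:
                heights.append(100 * e.adjusted_clamped)
                errs.append(100 * (e.ci_high - e.ci_low) / 2)
        ax.bar(x + i * width, heights, width, yerr=errs, capsize=2, label=cohort)
    ax.set_xticks(x + width * (len(cohorts) - 1) / 2)
    ax.set_xticklabels(categories, rotation=45, ha="right")
    ax.set_ylabel("adjusted prevalence (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def ehr_npi_stacked_bars(comparisons, out_path) -> None:
    """Stacked proportions of EHR+NPI+, EHR+NPI-, EHR-NPI+ per category."""
    categories = [c.category for c in comparisons]
    x = np.arange(len(categories))
    both, ehr_only, npi_only = [], [], []
    for c in comparisons:
        # reconstruct cell proportions from the comparison's summary fields
        ehr_pos = np.nan_to_num(c.prop_ehr_pos_npi_neg)
        npi_pos = np.nan_to_num(c.prop_ehr_neg_npi_pos)
        both.append(1 - ehr_pos)
        ehr_only.append(ehr_pos)
        npi_only.append(npi_pos)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(x, both, label="EHR+NPI+ (share of EHR+)")
    ax.bar(x, ehr_only, bottom=both, label="EHR+NPI- (share of EHR+)")
    ax.bar(x, npi_only, bottom=np.array(both) + np.array(ehr_only),
           label="EHR-NPI+ (share of NPI+)")
    ax.set_xticks(x)
    ax.set_xticklabels(categories, rotation=45, ha="right")
    ax.set_ylabel("proportion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
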