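"""Reference catalogs and headline figures from a published pooled analysis.

A pooled analysis of 1,163 Phase II oncology trials (53,745 subjects,
184 agents) produced catalogs of two-agent combinations with evidence of
clinical synergy and antagonism under the non-interaction null model this
package implements. Those printed catalogs and dataset-level figures are
embedded here as plain data: they serve as worked-example inputs (e.g.
counting monoclonal antibodies among the synergistic pairs) and as the
reference values a re-analysis of the full curated dataset — which is not
redistributed with this package — would be compared against. Figures that
require the full trial-level dataset to recompute are marked
``desk_scale=False``.

Each catalog row: (agent_1, agent_2, standard_of_care, expected ORR_1,
observed ORR_0, tail p-value, cancer subtype). ORRs are percentages
rounded to integers as printed; p-values are one-sided binomial tails.
"""

from __future__ import annotations

import pandas as pd

from .trial_io import AgentRegistry

__all__ = [
    "synergy_catalog",
    "antagonism_catalog",
    "reference_registry",
    "HEADLINE",
]

_CATALOG_COLUMNS = [
    "agent_1", "agent_2", "standard_of_care",
    "expected_orr1", "observed_orr0", "p_value", "cancer_subtype",
]

# Synergistic two-agent combinations (p_synergy ascending).
_SYNERGY_ROWS = [
    ("Docetaxel", "Doxorubicin", True, 40, 65, 7.70e-43, "Breast cancer"),
    ("Oxaliplatin", "5-fluorouracil", True, 25, 52, 1.82e-17, "Colorectal, gastric cancer"),
    ("Irinotecan", "Etoposide", False, 19, 66, 4.98e-13, "Lung cancer"),
    ("Doxorubicin", "Ifosfamide", True, 19, 48, 1.20e-09, "Gynecologic, soft tissue sarcoma"),
    ("Bortezomib", "Thalidomide", True, 56, 100, 2.13e-09, "Myeloma"),
    ("Capecitabine", "Irinotecan", False, 35, 48, 9.53e-09, "Colorectal, gastric, lung cancer"),
    ("S-1", "Irinotecan", False, 33, 47, 1.20e-07, "Colorectal, gastric, lung cancer"),
    ("Oxaliplatin", "Doxorubicin", False, 27, 68, 1.30e-07, "Ovarian cancer"),
    ("Oxaliplatin", "Irinotecan", True, 24, 52, 4.30e-06, "Colorectal, lung cancer"),
    ("Capecitabine", "Radiation", False, 65, 88, 3.11e-05, "Cervical cancer"),
    ("Rituximab", "Alpha-interferon", False, 67, 94, 2.48e-04, "Lymphoma"),
    ("Oxaliplatin", "Capecitabine", True, 38, 44, 3.41e-03, "Colorectal, gastric cancer"),
    ("5-fluorouracil", "Irinotecan", True, 22, 38, 5.87e-03, "Colorectal cancer"),
    ("Capecitabine", "Alpha-interferon", False, 38, 54, 3.34e-02, "Renal cancer"),
    ("Fludarabine", "Thalidomide", False, 78, 100, 4.05e-02, "Leukemia"),
]

# Antagonistic two-agent combinations (p_antagonism ascending).
_ANTAGONISM_ROWS = [
    ("Docetaxel", "Topotecan", False, 42, 12, 2.94e-11, "Lung, ovarian cancer"),
    ("Bortezomib", "Rituximab", False, 78, 53, 1.20e-09, "Lymphoma"),
    ("Temozolomide", "Alpha-interferon", False, 38, 18, 5.87e-08, "Melanoma"),
    ("Capecitabine", "Bortezomib", False, 58, 14, 9.02e-08, "Breast cancer"),
    ("Fludarabine", "Alemtuzumab", False, 83, 64, 1.27e-07, "CLL, leukemia"),
    ("Bevacizumab", "Temozolomide", False, 48, 16, 1.41e-07, "Melanoma"),
    ("Capecitabine", "Trimetrexate", False, 45, 6, 2.15e-06, "Colorectal cancer"),
    ("Docetaxel", "Irinotecan", False, 37, 18, 1.15e-05, "Gastric, lung, ovarian cancer"),
    ("Bortezomib", "Temsirolimus", False, 64, 30, 1.25e-05, "Myeloma"),
    ("Temozolomide", "Interleukin-2", False, 49, 16, 1.97e-05, "Melanoma"),
    ("Docetaxel", "Gefitinib", False, 71, 31, 2.29e-05, "Lung cancer"),
    ("Docetaxel", "5-fluorouracil", False, 38, 25, 1.71e-04, "Gastric, head and neck cancer"),
    ("Rituximab", "Temsirolimus", False, 75, 59, 2.44e-03, "Lymphoma"),
    ("Temozolomide", "Radiation", False, 64, 46, 2.51e-03, "Breast cancer"),
    ("Fludarabine", "Alpha-interferon", False, 76, 52, 2.55e-03, "Lymphoma"),
    ("G-CSF", "Rituximab", False, 71, 61, 4.69e-03, "CLL, lymphoma"),
    ("Doxorubicin", "Bevacizumab", False, 40, 21, 9.11e-03, "Breast cancer"),
    ("Docetaxel", "Imatinib", False, 46, 28, 2.09e-02, "Breast cancer"),
    ("Docetaxel", "Capecitabine", True, 49, 43, 4.48e-02, "Breast, gastric cancer"),
    ("Vinorelbine", "Mitoxantrone", False, 42, 29, 4.62e-02, "Breast cancer"),
]

# Dataset-level figures. desk_scale=False marks quantities recomputable only
# from the full curated trial table, which is not redistributed here.
HEADLINE = {
    "n_trials": {"value": 1163, "desk_scale": False},
    "n_subjects": {"value": 53745, "desk_scale": False},
    "n_agents": {"value": 184, "desk_scale": False},
    "n_combinations_tested": {"value": 514, "desk_scale": False},
    "n_mab_combinations": {"value": 85, "desk_scale": False},
    "n_multi_trial_combinations": {"value": 166, "desk_scale": False},
    "n_equivalent_combinations": {"value": 142, "desk_scale": False},
    "n_discordant_combinations": {"value": 24, "desk_scale": False},
    "ks_mab_vs_other_p": {"value": 0.0042, "desk_scale": False},
    "mab_mean_orr_percent": {"value": 54, "desk_scale": False},
    "non_mab_mean_orr_percent": {"value": 46, "desk_scale": False},
    "mab_enrichment_fisher_p": {"value": 0.99, "desk_scale": False},
    "loocv_underestimation_pct_size1": {"value": 77, "desk_scale": False},
    "loocv_underestimation_pct_size2": {"value": 76, "desk_scale": False},
    "loocv_underestimation_pct_size3plus": {"value": 69, "desk_scale": False},
    # Recomputable from the printed catalogs alone:
    "n_synergistic_pairs": {"value": 15, "desk_scale": True},
    "n_antagonistic_pairs": {"value": 20, "desk_scale": True},
    "n_synergy_pairs_with_mab": {"value": 1, "desk_scale": True},
    "n_antagonism_standard_of_care": {"value": 1, "desk_scale": True},
}


def synergy_catalog() -> pd.DataFrame:
    """Reference catalog of synergistic two-agent combinations."""
    return pd.DataFrame(_SYNERGY_ROWS, columns=_CATALOG_COLUMNS)


def antagonism_catalog() -> pd.DataFrame:
    """Reference catalog of antagonistic two-agent combinations."""
    return pd.DataFrame(_ANTAGONISM_ROWS, columns=_CATALOG_COLUMNS)


def reference_registry() -> AgentRegistry:
    """Registry covering every agent in the reference catalogs.

    Monoclonal antibodies are identified by the INN ``-mab`` suffix;
    alpha-interferon and interleukin-2 are cytokines, not antibodies, and
    radiation is registered as an agent because chemoradiation arms are
    treated as combinations.
    """
    reg = AgentRegistry()
    agents = set()
    for rows in (_SYNERGY_ROWS, _ANTAGONISM_ROWS):
        for r in rows:
            agents.update(r[:2])
    for name in sorted(agents):
        reg.register(name)  # mAb status falls back to the -mab suffix
    return reg
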