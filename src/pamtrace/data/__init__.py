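"""Published cohort summary tables from a five-case pancreatic-cancer rapid
autopsy study of tumor-specific PAM maintenance.

``wgs_subtractions`` holds, per tumor-normal whole-genome subtraction, the
number of passing somatic variants, the novel PAMs discovered, and the
subset with VAF >= 95% (high-VAF LOH candidates). ``case_maintenance``
holds the per-case capture-validation statistics: metastasis count,
truncal PAM count, mean percent maintained per PAM, mean percent truncal
per metastasis, and percent of truncal PAMs shared by all lesions.
"""

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def wgs_subtractions() -> pd.DataFrame:
    return _load("wgs_subtractions.tsv")


def case_maintenance() -> pd.DataFrame:
    return _load("case_maintenance.tsv")
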