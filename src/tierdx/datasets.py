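"""Bundled example data.

The packaged cohort is a fully reconstructed tertiary-center cohort of 72
unrelated probands with epilepsy and comorbid neurodevelopmental disorders
(NDD) or developmental and epileptic encephalopathy (DEE) who underwent a
stepwise "dynamic" exome workup: a first virtual gene panel, a broader
second-step reanalysis panel, and finally unrestricted exome analysis.
Twenty-one probands were diagnosed at tier 1, four at tier 2 and two at
tier 3 (overall yield 27/72 = 37.5%); 45 remained undiagnosed.  Diagnosed
probands carry gene, genotype class, sex, age and phenotype annotations;
the undiagnosed carry synthetic ids U01..U45 with no annotations.
"""

from __future__ import annotations

from importlib.resources import files

from .cohort import Cohort, load_cohort

__all__ = ["epilepsy_ndd_cohort", "fixture_path"]


def fixture_path() -> str:
    """Filesystem path of the packaged cohort TSV."""
    return str(files("tierdx.data").joinpath("epilepsy_ndd_cohort.tsv"))


def epilepsy_ndd_cohort() -> Cohort:
    """The packaged 72-proband epilepsy/NDD cohort."""
    return load_cohort(fixture_path())
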