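import numpy as np
import pandas as pd
import pytest

from turnomix.io import ExperimentDesign
from turnomix.simulate import SimulationSpec


@pytest.fixture
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture
def design_cm() -> ExperimentDesign:
    return ExperimentDesign(conditions=("CM",))


def quiet_spec(**kwargs) -> SimulationSpec:
    """A spec with no planted structure unless asked for."""
    defaults = dict(frac_prolonged=0.0, frac_shortened=0.0,
                    n_planted_clients=0, n_interactors=0,
                    n_decoy_interactome=0, n_contaminants=0)
    defaults.update(kwargs)
    return SimulationSpec(**defaults)


def peptide_frame(rows) -> pd.DataFrame:
    """Build a peptide table from (protein, peptide, sample, light, heavy,
    contaminant) tuples; sample ids follow the genotype_condition_rN scheme."""
    out = []
    for protein, peptide, sample, light, heavy, contam in rows:
        g, c, r = sample.rsplit("_", 2)
        out.append(dict(protein_id=protein, peptide_seq=peptide,
                        sample_id=sample, genotype=g, condition=c,
                        replicate=int(r.lstrip("r")), light_intensity=light,
                        heavy_intensity=heavy, is_contaminant=contam))
    return pd.DataFrame(out)


def halflife_matrix(values: dict, design: ExperimentDesign) -> pd.DataFrame:
    """Protein x sample matrix from {protein: {genotype: [per-replicate]}}
    for a single-condition design."""
    cond = design.conditions[0]
    cols = design.sample_ids(cond)
    data = {}
    for pid, per_geno in values.items():
        row = []
        for g in design.genotypes:
            row.extend(per_geno[g])
        data[pid] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
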