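import numpy as np
import pandas as pd
import pytest

from histoptm import peptide_map as pm
from histoptm import quantify as q
from histoptm import synthetic_data as sd


@pytest.fixture(scope="session")
def synthetic_db(tmp_path_factory):
    """The synthetic histone database as parsed ProteinEntry objects."""
    path = tmp_path_factory.mktemp("db") / "histones.fasta"
    sd.write_synthetic_fasta(path)
    return pm.read_fasta(path)


@pytest.fixture(scope="session")
def peptide_map_bundle(synthetic_db):
    """(peptide map table, protein groups, peptides) over the synthetic db."""
    return pm.build_peptide_map(synthetic_db, max_missed=2)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Full study design at CV=0 with no missing values: quantification
    must recover ground truth exactly."""
    cfg = sd.preset_study(seed=11, noise_cv=0.0, missing_rate=0.0, n_replicates=2)
    areas, meta, truth = sd.gen_peak_areas(cfg)
    return areas, meta, truth


@pytest.fixture(scope="session")
def family_of_group(peptide_map_bundle):
    _, groups, _ = peptide_map_bundle
    return {g.display_name: g.family.value for g in groups}


def make_peptidoform(sequence, start=1, mods=(), nterm_prop=False):
    """Helper: a peptidoform on a standalone peptide."""
    pep = pm.Peptide(
        parent_ids=frozenset({"X"}),
        start=start,
        end=start + len(sequence) - 1,
        sequence=sequence,
        missed_cleavages=0,
    )
    return pm.Peptidoform(peptide=pep, modifications=tuple(mods), nterm_prop=nterm_prop)
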