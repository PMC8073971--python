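import pathlib

import pytest

from omseval.cli import run_search
from omseval.proteome import build_peptide_sets, make_decoy, read_fasta
from omseval.spectra import generate_spectrum
from omseval.synthetic import EditSpec, worked_example_fixture, generate_proteome, plant_edits

#: study conditions for the planted-modification experiment: a ~50-protein
#: synthetic proteome and 100 planted single edits, one fixed seed.
STUDY_SEED = 1
N_PROTEINS = 50
N_PLANTED = 100


@pytest.fixture(scope="session")
def worked_example_spectra():
    bait, hit = worked_example_fixture()
    return generate_spectrum(bait), generate_spectrum(hit)


@pytest.fixture(scope="session")
def planted_study(tmp_path_factory):
    """Full pipeline run on a synthetic proteome with planted single edits.

    Returns a dict with the peptide sets, the planted truth table, the
    candidate list and the best PSMs of both strategies.
    """
    fasta = tmp_path_factory.mktemp("study") / "proteome.fasta"
    fasta.write_text(generate_proteome(n_proteins=N_PROTEINS, seed=STUDY_SEED))
    proteins = read_fasta(fasta)
    bait_set, database = build_peptide_sets(proteins, make_decoy(proteins))
    planted, truth = plant_edits(
        bait_set,
        EditSpec(kind="single", n_baits=N_PLANTED, seed=STUDY_SEED + 1),
        forbidden={p.sequence for p in database},
    )
    baits = list(bait_set) + list(planted)
    best2, bait_spectra, db_spectra, candidates = run_search(baits, database, strategy=2)
    best1, _, _, _ = run_search(baits, database, strategy=1)
    return {
        "fasta": pathlib.Path(fasta),
        "bait_peptides": baits,
        "db_peptides": database,
        "truth": truth,
        "candidates": candidates,
        "best1": best1,
        "best2": best2,
        "bait_spectra": bait_spectra,
        "db_spectra": db_spectra,
    }
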