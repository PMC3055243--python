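import numpy as np
import pytest

from xyconv.alignio import Alignment, TaxonLabel, read_species_tree
from xyconv.conversion_scan import map_events, scan_topologies, segment_subregions
from xyconv.distances import WindowSpec
from xyconv.synthsim import PRIMATE_NEWICK, make_paper_fixture


def make_alignment(names_and_rows):
    from xyconv.alignio import parse_taxon_label

    names, rows = zip(*names_and_rows)
    return Alignment([parse_taxon_label(n) for n in names], list(rows))


@pytest.fixture(scope="session")
def primate_tree():
    return read_species_tree(PRIMATE_NEWICK)


@pytest.fixture(scope="session")
def fig3_run(primate_tree):
    """fig3 fixture analysed once: (aln, truth, calls, subregions, events)."""
    aln, truth = make_paper_fixture("fig3_ten_events", seed=11)
    calls = scan_topologies(aln, WindowSpec(2000, 2000), n_reps=100, seed=99)
    subregions = segment_subregions(calls)
    events = map_events(subregions, primate_tree, aln=aln)
    return aln, truth, calls, subregions, events


@pytest.fixture(scope="session")
def null_fixture():
    return make_paper_fixture("regionA_null", seed=7)


@pytest.fixture(scope="session")
def gibbon_fixture():
    return make_paper_fixture("fig4_gibbon", seed=5)
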