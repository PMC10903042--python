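import numpy as np
import pytest

import stressmark as sm
from stressmark.core_io import FragmentCollection, LibraryLabel


@pytest.fixture()
def chip_label():
    return LibraryLabel("C", 0, 1, "chip")


@pytest.fixture()
def input_label():
    return LibraryLabel("C", None, 1, "input")


def make_fragments(starts, genome, label=None, fragment_size=300):
    """Fragment collection from 5'-start positions on single or multiple chroms."""
    label = label or LibraryLabel("C", 0, 1, "chip")
    if isinstance(starts, dict):
        by_chrom = {
            c: np.stack([np.sort(np.asarray(s)),
                         np.sort(np.asarray(s)) + fragment_size], axis=1).astype(np.int64)
            for c, s in starts.items()
        }
    else:
        arr = np.sort(np.asarray(starts))
        chrom = next(iter(genome))
        by_chrom = {chrom: np.stack([arr, arr + fragment_size], axis=1).astype(np.int64)}
    return FragmentCollection(label=label, by_chrom=by_chrom, genome=dict(genome))


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """Default synthetic experiment run end-to-end through the pipeline."""
    d = tmp_path_factory.mktemp("e2e")
    spec = sm.TruthSpec(seed=7)
    truth = sm.simulate_experiment(spec, d)
    cfg = sm.PipelineConfig()
    genome = sm.read_genome_tsv(d / "genome.tsv")
    frags = sm.load_experiment(d / "manifest.tsv", genome, cfg)
    peaksets, universe, responsive = sm.run_stress_classification(frags, genome, cfg)
    ann = sm.read_gff3_genes(d / "annotation.gff3", repeats_bed=d / "repeats.bed")
    return {
        "dir": d, "spec": spec, "truth": truth, "cfg": cfg, "genome": genome,
        "frags": frags, "peaksets": peaksets, "universe": universe,
        "responsive": responsive, "annotation": ann,
    }
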