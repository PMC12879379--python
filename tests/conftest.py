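import numpy as np
import pandas as pd
import pytest

from cisgrammar import library as lib
from cisgrammar.activity import parse_slots
from cisgrammar.motifs import PPM


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ppm(rng, motif_id="m", length=8, sharp=False, source="novel"):
    """A random PPM; ``sharp=True`` concentrates each column on one letter."""
    if sharp:
        mat = rng.dirichlet([0.2, 0.2, 0.2, 0.2], size=length)
    else:
        mat = rng.dirichlet([1.0, 1.0, 1.0, 1.0], size=length)
    return PPM(motif_id, mat, source=source)


def consensus_ppm(seq, motif_id="m", p=0.97, source="novel"):
    """A near-one-hot PPM around a consensus sequence."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((len(seq), 4), (1 - p) / 3)
    for j, b in enumerate(seq):
        mat[j, idx[b]] = p
    return PPM(motif_id, mat, source=source)


@pytest.fixture
def toy_sites():
    # distinct, non-palindromic 12-mer sites
    return {"MA": "GATCCGGATTAC", "MB": "TTGACGTCAGCA"}


@pytest.fixture
def toy_background():
    return "".join(np.random.default_rng(9).choice(list("ACGT"), 125))


@pytest.fixture
def toy_manifest(toy_sites, toy_background):
    import warnings

    with warnings.catch_warnings():
        # equivalent packings of empty slots collide on sequence by design
        warnings.simplefilter("ignore")
        manifest = lib.build_library(toy_sites, toy_background)
    return manifest


@pytest.fixture
def toy_slots(toy_manifest):
    return parse_slots(toy_manifest)


@pytest.fixture
def background_oligo_id(toy_manifest):
    slot_cols = [c for c in toy_manifest.columns if c.startswith("slot")]
    empty = (toy_manifest[slot_cols] == ".").all(axis=1) & ~toy_manifest["is_control"]
    return toy_manifest.loc[empty, "oligo_id"].item()


def brute_force_components(kmers):
    """O(n^2) connected components of the Hamming<=1 graph (oracle)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(kmers)
    ks = list(kmers)
    for i in range(len(ks)):
        for j in range(i + 1, len(ks)):
            if sum(a != b for a, b in zip(ks[i], ks[j])) <= 1:
                g.add_edge(ks[i], ks[j])
    return {frozenset(c) for c in nx.connected_components(g)}
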