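import os
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))  # for _oracles

from kmerdecon import KmerSpace, build_reference
from kmerdecon.simulate import (
    SimulationSpec,
    generate_genomes,
    generate_reads,
)

settings.register_profile(
    "package",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def space7() -> KmerSpace:
    return KmerSpace(7)


def write_fasta(path, records) -> str:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return str(path)


@pytest.fixture(scope="session")
def community3(tmp_path_factory):
    """Three 5 kb synthetic genomes on disk, two sharing a genus.

    Returns a dict with the built k=7 reference, genome sequences, ids,
    FASTA paths and the taxonomy table.
    """
    root = tmp_path_factory.mktemp("community3")
    rng = np.random.default_rng(101)
    ids = ["gA", "gB", "gC"]
    genomes = {
        gid: "".join(
            "ACGT"[i] for i in rng.integers(0, 4, 5000)
        )
        for gid in ids
    }
    labels = {
        "gA": {"kingdom": "Bacteria", "genus": "Shared", "species": "spA"},
        "gB": {"kingdom": "Bacteria", "genus": "Shared", "species": "spB"},
        "gC": {"kingdom": "Bacteria", "genus": "Solo", "species": "spC"},
    }
    paths = {}
    triples = []
    for gid in ids:
        p = write_fasta(root / f"{gid}.fasta", [(gid, genomes[gid])])
        paths[gid] = p
        triples.append((gid, p, labels[gid]))
    db = build_reference(triples, k=7)
    return {
        "db": db,
        "genomes": genomes,
        "ids": ids,
        "paths": paths,
        "labels": labels,
        "dir": root,
    }


@pytest.fixture(scope="session")
def scaled_community(tmp_path_factory):
    """The scaled five-genome study mixture: 50 kb genomes, 100 nt reads.

    Provides the reference database, 100,000 error-free reads drawn at
    proportions (0.40, 0.25, 0.20, 0.10, 0.05), and the realized truth.
    Shared session-wide because generation is the expensive part.
    """
    from kmerdecon.simulate import truth_proportions

    root = tmp_path_factory.mktemp("scaled")
    spec = SimulationSpec(n_reads=100_000, error_rate=0.0, seed=20_140_605)
    genomes = generate_genomes(spec)
    reads, truth = generate_reads(spec, genomes)
    ids = spec.genome_ids()
    triples = []
    for gid, g in zip(ids, genomes):
        p = write_fasta(root / f"{gid}.fasta", [(gid, g)])
        triples.append(
            (gid, p, {"genus": f"genus_{gid}", "species": f"sp_{gid}"})
        )
    db = build_reference(triples, k=7)
    return {
        "spec": spec,
        "genomes": genomes,
        "reads": reads,
        "truth": truth,
        "truth_p": truth_proportions(truth, ids),
        "db": db,
        "ids": ids,
        "dir": root,
    }
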