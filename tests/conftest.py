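"""Shared fixtures: synthetic genomes are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from plastokit.architecture import detect_quadripartite
from plastokit.records import CircularSequence
from plastokit.simulate import paper_config, simulate_plastome

SPECIES = ("U_pinnatifida", "S_japonica", "E_siliculosus", "F_vesiculosus")


@pytest.fixture(scope="session")
def four_records():
    return {sp: simulate_plastome(paper_config(sp, seed=1)) for sp in SPECIES}


@pytest.fixture(scope="session")
def up_record(four_records):
    return four_records["U_pinnatifida"]


@pytest.fixture(scope="session")
def sj_record(four_records):
    return four_records["S_japonica"]


@pytest.fixture(scope="session")
def up_quadripartite(up_record):
    return detect_quadripartite(up_record.sequence, min_ir=1000)


def random_circle(rng: np.random.Generator, length: int, name: str = "fuzz",
                  at: float = 0.5) -> CircularSequence:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    residues = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return CircularSequence(residues, name=name, is_circular=True)


def plant_inverted_repeat(rng: np.random.Generator, length: int, ir_len: int,
                          gap: int) -> CircularSequence:
    """Random circle with one planted exact inverted-repeat pair."""
    from plastokit.records import reverse_complement

    core = random_circle(rng, length).residues
    ir = "".join(rng.choice(list("ACGT"), size=ir_len))
    pos_b = ir_len + gap
    seq = ir + core[ir_len:pos_b] + reverse_complement(ir) + core[pos_b + ir_len:]
    return CircularSequence(seq[:length], name="planted", is_circular=True)
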