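from __future__ import annotations

import numpy as np
import pytest

from strandslip import (
    AtomRecord,
    Domain,
    Residue,
    SyntheticDomainSpec,
    generate_domain,
)
from strandslip.model import ONE_TO_THREE


def domain_from_model(model, label="domain"):
    """All protein residues of a single-chain model as one Domain."""
    return Domain(label, model.chains[0].residues)


def make_twin_pair(
    seed: int,
    shift_segments,
    noise_sigma: float = 0.0,
    strand_length: int = 8,
    **kwargs,
):
    """Baseline domain and its register-shifted twin on the same scaffold.

    The twin gets an independent noise stream (distinct noise seed) so the
    coordinate errors of the two structures are uncorrelated.
    """
    spec_a = SyntheticDomainSpec(
        seed=seed, noise_sigma=noise_sigma, strand_length=strand_length, **kwargs
    )
    spec_b = SyntheticDomainSpec(
        seed=seed,
        shift_segments=list(shift_segments),
        noise_sigma=noise_sigma,
        noise_seed=seed + 50_000,
        strand_length=strand_length,
        **kwargs,
    )
    model_a, truth_a = generate_domain(spec_a)
    model_b, truth_b = generate_domain(spec_b)
    return (
        domain_from_model(model_a, "baseline"),
        domain_from_model(model_b, "twin"),
        truth_b,
    )


def domain_from_sequence(seq: str, coords=None, label="seq-domain") -> Domain:
    """A minimal Cα-only domain with the given one-letter sequence."""
    if coords is None:
        coords = [(3.8 * i, 0.0, 0.0) for i in range(len(seq))]
    residues = []
    for i, (one, xyz) in enumerate(zip(seq, coords), start=1):
        res = Residue(
            chain_id="A",
            seq_number=i,
            insertion_code="",
            res_name=ONE_TO_THREE.get(one, "UNK"),
        )
        res.atoms.append(AtomRecord(serial=i, name="CA", element="C", alt_loc="", coords=np.asarray(xyz, float)))
        residues.append(res)
    return Domain(label, residues)


@pytest.fixture
def baseline_domain():
    model, _ = generate_domain(SyntheticDomainSpec(seed=1))
    return domain_from_model(model, "baseline")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
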