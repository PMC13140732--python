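"""Seeded synthetic peptide corpora.

Emulates the statistical structure of a small curated set of short
helical peptides: ~81 unique sequences, lengths uniform on 8-20,
residue composition biased towards helix-favouring amino acids, an
optional conserved motif implanted in a fraction of the sequences, and
mutual pairwise identity kept below a cap (30% by default) by
rejection resampling.  Every corpus is fully reproducible from its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import AMINO_ACIDS, PeptideRecord, pairwise_identity

#: Helix-biased sampling weights: residues favoured in alpha helices
#: (A, L, E, K, Q, M, R) are up-weighted 2x, helix breakers (G, P)
#: down-weighted to 0.3, all others weight 1.
HELIX_COMPOSITION: dict[str, float] = {
    **{aa: 1.0 for aa in AMINO_ACIDS},
    **{aa: 2.0 for aa in "ALEKQMR"},
    **{aa: 0.3 for aa in "GP"},
}

#: Default implanted motif: a 5-mer drawn from the QK reference peptide.
DEFAULT_MOTIF = "WQELY"

#: Sequences printed in the source study: the lead designed peptide
#: VMP3 and the QK reference (a VEGF-mimetic 15-mer from the
#: receptor-binding helix of VEGF-A).
VMP3_SEQUENCE = "ARFLEVWQRTYCKA"
QK_SEQUENCE = "KLTWQELYQLKYKGI"


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Attributes
    ----------
    n_peptides : int
        Number of sequences to generate (default 81).
    min_len, max_len : int
        Inclusive length band; lengths are uniform on it.
    composition : dict[str, float]
        Residue sampling weights (non-negative, not all zero).
    motif : str or None
        Short sequence implanted with probability ``motif_probability``
        at a uniform random valid offset; ``None`` disables implanting.
    motif_probability : float
        Per-peptide implantation probability (default 0.5).
    identity_cap : float
        Rejection-sampling cap on pairwise identity (default 0.30).
    seed : int
        RNG seed; corpora are byte-identical given the same spec.
    """

    n_peptides: int = 81
    min_len: int = 8
    max_len: int = 20
    composition: dict[str, float] = field(
        default_factory=lambda: dict(HELIX_COMPOSITION)
    )
    motif: str | None = DEFAULT_MOTIF
    motif_probability: float = 0.5
    identity_cap: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError(
                f"invalid length band ({self.min_len}, {self.max_len})"
            )
        weights = [self.composition.get(aa, 0.0) for aa in AMINO_ACIDS]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("composition weights must be non-negative and not all zero")
        if not 0.0 < self.identity_cap <= 1.0:
            raise ValueError("identity_cap must be in (0, 1]")
        if not 0.0 <= self.motif_probability <= 1.0:
            raise ValueError("motif_probability must be in [0, 1]")
        if self.motif is not None and len(self.motif) > self.max_len:
            raise ValueError("motif longer than max_len")


_MAX_CONSECUTIVE_REJECTIONS = 1000


def sample_corpus(spec: CorpusSpec) -> list[PeptideRecord]:
    """Draw a synthetic corpus satisfying ``spec``.

    Residues are i.i.d. from the composition; the motif, when drawn,
    overwrites a uniformly chosen window.  Candidates whose identity
    with any already-accepted peptide reaches ``identity_cap`` are
    rejected and resampled.

    Raises
    ------
    RuntimeError
        After 1000 consecutive rejections (the identity cap is too
        tight for the requested corpus).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = list(AMINO_ACIDS)
    probs = np.array([spec.composition.get(aa, 0.0) for aa in AMINO_ACIDS])
    probs = probs / probs.sum()

    kept: list[PeptideRecord] = []
    failures = 0
    while len(kept) < spec.n_peptides:
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        residues = list(rng.choice(alphabet, size=length, p=probs))
        if (
            spec.motif
            and length >= len(spec.motif)
            and rng.random() < spec.motif_probability
        ):
            offset = int(rng.integers(0, length - len(spec.motif) + 1))
            residues[offset : offset + len(spec.motif)] = list(spec.motif)
        seq = "".join(residues)
        # a cap of 1.0 disables the constraint (identity is at most 1)
        if spec.identity_cap >= 1.0 or all(
            pairwise_identity(seq, k.sequence) < spec.identity_cap
            for k in kept
        ):
            kept.append(
                PeptideRecord(
                    id=f"syn{len(kept) + 1:03d}",
                    sequence=seq,
                    source="synthetic",
                )
            )
            failures = 0
        else:
            failures += 1
            if failures >= _MAX_CONSECUTIVE_REJECTIONS:
                raise RuntimeError(
                    f"rejection sampling stalled after {failures} consecutive "
                    f"failures at {len(kept)}/{spec.n_peptides} peptides; "
                    f"loosen identity_cap (currently {spec.identity_cap})"
                )
    return kept


def fixture_sequences() -> list[PeptideRecord]:
    """The two peptides printed in the source study's sequence table.

    VMP3 (the designed lead, 14 residues) and QK (the VEGF-mimetic
    reference, 15 residues).
    """
    return [
        PeptideRecord(id="VMP3", sequence=VMP3_SEQUENCE, source="fixture"),
        PeptideRecord(id="QK", sequence=QK_SEQUENCE, source="fixture"),
    ]
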