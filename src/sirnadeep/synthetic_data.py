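"""Seeded generator of siRNA-like records with a known, recoverable signal.

Each synthetic record mimics the shape of a curated silencing-efficacy
entry: a random mRNA context around a 21-nt binding site, the guide strand
as its reverse complement, and an efficacy built from a latent score

    latent = motif_effect · 1[motif planted] + thermo_effect · ΔΔG_ends + ε,
    efficacy = sigmoid(latent),         ε ~ Normal(0, noise_sd²)

so a sequence-context signal (a short motif planted in the flanks of a
random half of the records) and a thermodynamic end-asymmetry signal are
both present and both recoverable.  The sigmoid link keeps efficacies in
(0, 1), the model's own output range.  Ground truth is returned as a
sidecar table so tests never re-derive it from the generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sirnadeep.records_io import GUIDE_LEN, SiRNARecord, reverse_complement, normalize_rna
from sirnadeep.thermo import CORE_LEN, NNParameterTable, end_differential

_BASES = np.array(list("AUGC"))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_records: int = 2000
    flank_n: int = 20
    motif: str = "GCGAUCGC"
    motif_effect: float = 3.0
    thermo_effect: float = 1.0
    noise_sd: float = 0.1
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25)  # A, U, G, C
    seed: int = 0
    #: fraction of records that carry the planted motif
    motif_prob: float = 0.5
    #: distance (nt) from the motif start upstream to the binding-region
    #: start; None places the motif uniformly at random within a flank
    motif_position: Optional[int] = None

    def __post_init__(self) -> None:
        self.motif = normalize_rna(self.motif) if self.motif else ""
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motif and len(self.motif) > self.flank_n:
            raise ValueError(
                f"motif length {len(self.motif)} exceeds flank length {self.flank_n}"
            )
        if self.motif_position is not None and not (
            len(self.motif) <= self.motif_position <= self.flank_n
        ):
            raise ValueError("motif_position must fit the motif inside the upstream flank")


def generate(
    spec: SyntheticSpec, params: NNParameterTable
) -> tuple[list, pd.DataFrame]:
    """Draw records and their ground-truth signal table, deterministically.

    Contexts are i.i.d. draws from ``base_composition``; the motif, when
    planted, overwrites flank positions (upstream at ``motif_position``
    when given, otherwise a uniformly random slot in either flank).
    """
    rng = np.random.default_rng(spec.seed)
    ctx_len = GUIDE_LEN + 2 * spec.flank_n
    comp = np.asarray(spec.base_composition, dtype=float)
    records = []
    truth_rows = []
    for i in range(spec.n_records):
        ctx = rng.choice(_BASES, size=ctx_len, p=comp)
        carries = bool(spec.motif) and (rng.random() < spec.motif_prob)
        motif_start = -1
        if carries:
            mlen = len(spec.motif)
            if spec.motif_position is not None:
                motif_start = spec.flank_n - spec.motif_position
            else:
                # uniformly random slot fully inside one of the two flanks
                up_slots = spec.flank_n - mlen + 1
                slot = int(rng.integers(0, 2 * up_slots))
                if slot < up_slots:
                    motif_start = slot
                else:
                    motif_start = spec.flank_n + GUIDE_LEN + (slot - up_slots)
            ctx[motif_start : motif_start + len(spec.motif)] = list(spec.motif)
        context = "".join(ctx)
        binding = context[spec.flank_n : spec.flank_n + GUIDE_LEN]
        guide = reverse_complement(binding)
        dd_ends = end_differential(guide[:CORE_LEN], params)
        eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        latent = spec.motif_effect * carries + spec.thermo_effect * dd_ends + eps
        efficacy = float(_sigmoid(latent))
        rid = f"syn{i:05d}"
        records.append(
            SiRNARecord(
                id=rid,
                guide_seq=guide,
                target_context=context,
                binding_offset=spec.flank_n,
                efficacy=efficacy,
                source_tag="synthetic",
            )
        )
        truth_rows.append(
            {
                "id": rid,
                "motif_present": int(carries),
                "motif_start": motif_start,
                "end_differential": dd_ends,
                "latent": latent,
                "efficacy": efficacy,
            }
        )
    return records, pd.DataFrame(truth_rows)
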