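"""Nearest-neighbor thermodynamics of the siRNA duplex.

Twenty descriptors per siRNA, computed from the guide (antisense) strand
under a perfect-match assumption:

* duplex hybridization stability ΔG (1 value),
* differential stability of the two duplex ends (1 value) — the asymmetry
  implicated in guide-strand selection,
* the per-dinucleotide-step ΔG profile along the antisense strand
  (18 values).

Eighteen steps force a 19-nt duplexed core, consistent with canonical
21-mers carrying 2-nt 3' overhangs: the trailing 2 nt of the 21-mer are
excluded from the thermodynamics.  ΔG parameters come from a bundled
published RNA/RNA nearest-neighbor table (ΔG°37, kcal/mol) or any
user-supplied table of the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np

from sirnadeep.records_io import SiRNARecord, normalize_rna

CORE_LEN = 19  # duplexed core of the 21-mer (18 dinucleotide steps)
N_STEPS = CORE_LEN - 1
N_FEATURES = 20

_ALL_STEPS = ["".join(p) for p in product("ACGU", repeat=2)]


@dataclass
class NNParameterTable:
    """Dinucleotide-step ΔG map plus initiation and terminal-AU terms."""

    step_dg: dict
    init_dg: float
    terminal_au_penalty: float = 0.0

    def __post_init__(self) -> None:
        self.step_dg = {normalize_rna(k): float(v) for k, v in self.step_dg.items()}
        missing = set(_ALL_STEPS) - set(self.step_dg)
        if missing:
            raise ValueError(f"parameter table missing steps: {sorted(missing)}")
        vals = list(self.step_dg.values()) + [self.init_dg, self.terminal_au_penalty]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameter table contains non-finite values")

    @classmethod
    def from_tsv(cls, path) -> "NNParameterTable":
        """Load a `step<TAB>dg_kcal_mol` table with #init_dg / #terminal_au headers."""
        step_dg = {}
        init_dg = 0.0
        terminal_au = 0.0
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#init_dg="):
                        init_dg = float(line.split("=", 1)[1])
                    elif line.startswith("#terminal_au="):
                        terminal_au = float(line.split("=", 1)[1])
                    continue
                parts = line.split("\t")
                if parts[0].lower() == "step":
                    continue
                step_dg[parts[0]] = float(parts[1])
        return cls(step_dg=step_dg, init_dg=init_dg, terminal_au_penalty=terminal_au)


def load_default_params() -> NNParameterTable:
    """The bundled published RNA/RNA ΔG°37 nearest-neighbor table."""
    ref = resources.files("sirnadeep.data") / "xia1998_rna_nn_dg37.tsv"
    with resources.as_file(ref) as path:
        return NNParameterTable.from_tsv(path)


@dataclass
class ThermoFeatures:
    duplex_dg: float
    end_differential: float
    step_profile: np.ndarray

    def flatten(self) -> np.ndarray:
        """Ordered 20-vector: (duplex_dg, end_differential, 18-step profile)."""
        out = np.concatenate(([self.duplex_dg, self.end_differential], self.step_profile))
        assert out.shape == (N_FEATURES,)
        return out


def _core(guide_core: str) -> str:
    s = normalize_rna(guide_core)
    if len(s) != CORE_LEN:
        raise ValueError(f"guide core must be {CORE_LEN} nt, got {len(s)}")
    return s


def step_profile(guide_core: str, params: NNParameterTable) -> np.ndarray:
    """ΔG of each of the 18 dinucleotide steps along the antisense strand."""
    s = _core(guide_core)
    return np.array([params.step_dg[s[j : j + 2]] for j in range(N_STEPS)])


def duplex_stability(guide_core: str, params: NNParameterTable) -> float:
    """Total hybridization ΔG: initiation + step sum + terminal AU penalties."""
    s = _core(guide_core)
    dg = params.init_dg + float(step_profile(s, params).sum())
    for end in (s[0], s[-1]):
        if end in ("A", "U"):
            dg += params.terminal_au_penalty
    return dg


def end_differential(guide_core: str, params: NNParameterTable, end_window: int = 1) -> float:
    """ΔG(5' end of the antisense strand) − ΔG(3' end).

    Each end is summarised by its ``end_window`` terminal dinucleotide
    steps (default 1).  A negative value means the 5' (seed-proximal) end
    of the guide is the more stable one.
    """
    if not (1 <= end_window <= 9):
        raise ValueError(f"end_window must be in [1, 9], got {end_window}")
    prof = step_profile(guide_core, params)
    return float(prof[:end_window].sum() - prof[-end_window:].sum())


def featurize_thermo(
    record: SiRNARecord, params: NNParameterTable, end_window: int = 1
) -> ThermoFeatures:
    """The full ordered 20-descriptor thermodynamic vector for one record."""
    core = record.guide_seq[:CORE_LEN]
    return ThermoFeatures(
        duplex_dg=duplex_stability(core, params),
        end_differential=end_differential(core, params, end_window=end_window),
        step_profile=step_profile(core, params),
    )
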