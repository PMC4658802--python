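"""Nearest-neighbor energy model for miRNA:mRNA duplexes.

The duplex free energy is a sum of helix-step stacking terms, interior
loop/bulge penalties and a small cost for unpaired guide-terminal bases.
Parameters live in a YAML file so published nearest-neighbor sets can be
substituted; :func:`EnergyModel.default` loads the table shipped with the
package.  The same object also carries the weighted base-pair-maximization
parameters used by the simplified intramolecular fold (site accessibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
N_CODE = 4  # any non-ACGU character; never pairs

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU_PAIRS = {("G", "U"), ("U", "G")}
ALL_PAIRS = WC_PAIRS | GU_PAIRS


def pair_kind(a: str, b: str) -> str | None:
    """Classify a putative base pair: ``"wc"``, ``"gu"`` or ``None``."""
    if (a, b) in WC_PAIRS:
        return "wc"
    if (a, b) in GU_PAIRS:
        return "gu"
    return None


def encode_sequence(seq: str) -> np.ndarray:
    """Map an RNA string to int8 codes (A=0, C=1, G=2, U=3, other=4)."""
    return np.array([BASE_INDEX.get(c, N_CODE) for c in seq], dtype=np.int8)


def _symmetric_key(key: str) -> str:
    # XY/ZW read from the other duplex end is WZ/YX
    x, y = key[0], key[1]
    z, w = key[3], key[4]
    return f"{w}{z}/{y}{x}"


@dataclass
class EnergyModel:
    """Parameter container for duplex and fold energetics.

    Attributes
    ----------
    stacks : dict
        Helix-step energies keyed ``"XY/ZW"`` (top 5'-XY-3', bottom 3'-ZW-5').
        The table is symmetry-completed at load time.
    loop_init, loop_ext : float
        Interior-loop/bulge penalty ``init + ext * (L - 1)`` for a loop with
        ``L = max(unpaired_guide, unpaired_target) >= 1``.
    loop_max : int
        Largest number of unpaired bases allowed on either strand of one loop.
    end_penalty : float
        Per-base cost of unpaired guide-terminal nucleotides.
    """

    stacks: dict[str, float]
    loop_init: float = 3.2
    loop_ext: float = 0.6
    loop_max: int = 10
    end_penalty: float = 0.2
    duplex_init: float = 0.0
    fold_wc: float = -2.0
    fold_gu: float = -1.0
    fold_min_hairpin: int = 3
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "EnergyModel":
        stacks = dict(cfg.get("stacks", {}))
        gu_default = float(cfg.get("gu_default", -0.5))
        # complete by symmetry, then fill remaining wobble steps
        for key in list(stacks):
            sym = _symmetric_key(key)
            stacks.setdefault(sym, stacks[key])
        for p1 in ALL_PAIRS:
            for p2 in ALL_PAIRS:
                key = f"{p1[0]}{p2[0]}/{p1[1]}{p2[1]}"
                if key not in stacks:
                    if p1 in WC_PAIRS and p2 in WC_PAIRS:
                        raise ValueError(f"missing Watson-Crick stack {key}")
                    stacks[key] = gu_default
        loop = cfg.get("loop", {})
        fold = cfg.get("fold", {})
        model = cls(
            stacks=stacks,
            loop_init=float(loop.get("init", 3.2)),
            loop_ext=float(loop.get("ext", 0.6)),
            loop_max=int(loop.get("max_len", 10)),
            end_penalty=float(cfg.get("end_penalty", 0.2)),
            duplex_init=float(cfg.get("duplex_init", 0.0)),
            fold_wc=float(fold.get("wc", -2.0)),
            fold_gu=float(fold.get("gu", -1.0)),
            fold_min_hairpin=int(fold.get("min_hairpin", 3)),
        )
        model._validate()
        return model

    @classmethod
    def from_yaml(cls, path) -> "EnergyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EnergyModel":
        text = resources.files("mircurve.data").joinpath("energy_default.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def _validate(self) -> None:
        for p1 in WC_PAIRS:
            for p2 in WC_PAIRS:
                key = f"{p1[0]}{p2[0]}/{p1[1]}{p2[1]}"
                if self.stacks[key] >= 0:
                    raise ValueError(f"WC/WC stack {key} must be negative")
        if self.loop_init < 0 or self.loop_ext < 0 or self.end_penalty < 0:
            raise ValueError("loop and end penalties must be >= 0")

    # -- lookups ---------------------------------------------------------
    def stack_energy(self, x1: str, y1: str, x2: str, y2: str) -> float:
        """Energy of stacking pair ``x2:y2`` on ``x1:y1`` (guide 5'->3')."""
        return self.stacks[f"{x1}{x2}/{y1}{y2}"]

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in ALL_PAIRS

    # -- dense arrays for the numba kernels ------------------------------
    def arrays(self):
        """Return (pairable[5,5] bool, stack[5,5,5,5] float64) code-indexed."""
        if "pairable" not in self._arrays:
            pairable = np.zeros((5, 5), dtype=np.bool_)
            stack = np.zeros((5, 5, 5, 5), dtype=np.float64)
            for (a, b) in ALL_PAIRS:
                pairable[BASE_INDEX[a], BASE_INDEX[b]] = True
            for (a, b) in ALL_PAIRS:
                for (c, d) in ALL_PAIRS:
                    stack[BASE_INDEX[a], BASE_INDEX[b], BASE_INDEX[c], BASE_INDEX[d]] = (
                        self.stack_energy(a, b, c, d)
                    )
            self._arrays["pairable"] = pairable
            self._arrays["stack"] = stack
        return self._arrays["pairable"], self._arrays["stack"]

    def fold_pair_energies(self) -> np.ndarray:
        """Code-indexed [5,5] pair energies for the simplified fold."""
        if "fold" not in self._arrays:
            w = np.zeros((5, 5), dtype=np.float64)
            for (a, b) in WC_PAIRS:
                w[BASE_INDEX[a], BASE_INDEX[b]] = self.fold_wc
            for (a, b) in GU_PAIRS:
                w[BASE_INDEX[a], BASE_INDEX[b]] = self.fold_gu
            self._arrays["fold"] = w
        return self._arrays["fold"]
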