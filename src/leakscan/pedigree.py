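"""Pedigree container and pedigree simulation.

A pedigree is an ordered list of animal records (id, sire, dam, generation,
litter) in topological order: parents always precede offspring, unknown
parents are coded 0. This ordering is what makes the tabular relationship
matrix and Henderson's inverse rules single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad ordering, unknown references)."""


class ConfigError(ValueError):
    """Invalid simulation or model configuration."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    animal_id, sire_id, dam_id : int arrays
        Animal identifiers (positive, unique) and parent identifiers
        (0 = unknown). Parents must appear before their offspring.
    generation : int array
        Discrete generation number; founders are generation 0.
    litter_id : int array
        Common-litter label (littermates share a dam and a birth event).
    """

    animal_id: np.ndarray
    sire_id: np.ndarray
    dam_id: np.ndarray
    generation: np.ndarray
    litter_id: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id, dtype=np.int64)
        self.sire_id = np.asarray(self.sire_id, dtype=np.int64)
        self.dam_id = np.asarray(self.dam_id, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.litter_id = np.asarray(self.litter_id, dtype=np.int64)
        self._index = {a: i for i, a in enumerate(self.animal_id)}
        self._validate()

    def _validate(self) -> None:
        if len(self._index) != self.n:
            raise PedigreeError("animal ids are not unique")
        if np.any(self.animal_id <= 0):
            raise PedigreeError("animal ids must be positive")
        for name, parents in (("sire", self.sire_id), ("dam", self.dam_id)):
            for row, p in enumerate(parents):
                if p == UNKNOWN:
                    continue
                j = self._index.get(p)
                if j is None:
                    raise PedigreeError(f"{name} {p} of animal {self.animal_id[row]} not in pedigree")
                if j >= row:
                    raise PedigreeError(f"{name} {p} does not precede animal {self.animal_id[row]}")
        founders = self.generation == 0
        if np.any((self.sire_id[founders] != UNKNOWN) | (self.dam_id[founders] != UNKNOWN)):
            raise PedigreeError("founders must have unknown parents")

    @property
    def n(self) -> int:
        return len(self.animal_id)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_id == UNKNOWN) & (self.dam_id == UNKNOWN)

    def rows(self, ids) -> np.ndarray:
        """Positional rows of the given animal ids (raises on unknown ids)."""
        try:
            return np.array([self._index[a] for a in np.asarray(ids)], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise PedigreeError(f"animal {exc.args[0]} not in pedigree") from None

    def parent_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per animal, -1 where unknown."""
        sire = np.array([self._index[p] if p != UNKNOWN else -1 for p in self.sire_id])
        dam = np.array([self._index[p] if p != UNKNOWN else -1 for p in self.dam_id])
        return sire, dam

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "sire_id": self.sire_id,
                "dam_id": self.dam_id,
                "generation": self.generation,
                "litter_id": self.litter_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = ["animal_id", "sire_id", "dam_id"]
        gen = df["generation"] if "generation" in df else _infer_generations(df)
        litter = df["litter_id"] if "litter_id" in df else np.arange(1, len(df) + 1)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), df[cols[2]].to_numpy(),
                   np.asarray(gen), np.asarray(litter))


def _infer_generations(df: pd.DataFrame) -> np.ndarray:
    gen = {}
    out = np.zeros(len(df), dtype=np.int64)
    for i, (a, s, d) in enumerate(zip(df["animal_id"], df["sire_id"], df["dam_id"])):
        g = 0
        if s != UNKNOWN:
            g = max(g, gen[s] + 1)
        if d != UNKNOWN:
            g = max(g, gen[d] + 1)
        gen[a] = g
        out[i] = g
    return out


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    n_dams_per_sire: int = 1,
    litter_size: int = 2,
    seed: int = 0,
) -> Pedigree:
    """Simulate a litter-structured, discrete-generation pedigree.

    Each generation, the previous generation is randomly partitioned into
    sires and dams (``n_dams_per_sire`` dams per sire); every sire × dam
    mating produces one litter of ``litter_size`` full sibs. With one dam
    per sire and litters of two the population size is constant.

    Founders are generation 0 with unknown parents, each in its own litter.
    Deterministic given ``seed``.
    """
    if n_founders < 2 or n_founders % 2:
        raise ConfigError("n_founders must be an even integer >= 2")
    if n_generations < 0 or n_dams_per_sire < 1 or litter_size < 1:
        raise ConfigError("invalid pedigree simulation counts")
    rng = np.random.default_rng(seed)

    animal, sire, dam, gen, litter = [], [], [], [], []
    next_id = 1
    next_litter = 1
    prev = []
    for f in range(n_founders):
        animal.append(next_id)
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        gen.append(0)
        litter.append(next_litter)
        prev.append(next_id)
        next_id += 1
        next_litter += 1

    for g in range(1, n_generations + 1):
        perm = rng.permutation(prev)
        n_sires = len(prev) // (1 + n_dams_per_sire)
        if n_sires < 1:
            raise ConfigError("previous generation too small to form a mating pair")
        sires = perm[:n_sires]
        dams = perm[n_sires : n_sires * (1 + n_dams_per_sire)]
        cur = []
        for k, s in enumerate(sires):
            for d in dams[k * n_dams_per_sire : (k + 1) * n_dams_per_sire]:
                for _ in range(litter_size):
                    animal.append(next_id)
                    sire.append(int(s))
                    dam.append(int(d))
                    gen.append(g)
                    litter.append(next_litter)
                    cur.append(next_id)
                    next_id += 1
                next_litter += 1
        prev = cur

    return Pedigree(np.array(animal), np.array(sire), np.array(dam),
                    np.array(gen), np.array(litter))
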