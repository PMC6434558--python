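"""Nested paternal half-sib / maternal full-sib breeding designs.

The experimental unit hierarchy is temporal block -> sire -> dam ->
offspring, with each offspring assigned to one of two rearing-density
treatments (``high``/``low``) and a sex (``F``/``M``).  Sires are mated in
blocks (mating periods); dams are nested in sires; offspring of each dam
are split between the two density treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("high", "low")
SEXES = ("F", "M")


class DesignConfigError(ValueError):
    """Raised for impossible breeding-design configurations."""


@dataclass(frozen=True)
class BreedingDesign:
    """A realized block/sire/dam/offspring hierarchy.

    Attributes
    ----------
    blocks : list of str
        Block identifiers.
    sires : list of (str, str)
        ``(sire_id, block_id)`` pairs; each sire belongs to one block.
    dams : list of (str, str)
        ``(dam_id, sire_id)`` pairs; each dam is mated to one sire.
    offspring : list of (str, str, str, str)
        ``(individual_id, dam_id, treatment, sex)`` tuples.
    """

    blocks: list = field(default_factory=list)
    sires: list = field(default_factory=list)
    dams: list = field(default_factory=list)
    offspring: list = field(default_factory=list)

    def __post_init__(self):
        block_set = set(self.blocks)
        sire_block = dict(self.sires)
        dam_sire = dict(self.dams)
        if len(sire_block) != len(self.sires):
            raise DesignConfigError("duplicate sire ids")
        if len(dam_sire) != len(self.dams):
            raise DesignConfigError("duplicate dam ids")
        for s, b in self.sires:
            if b not in block_set:
                raise DesignConfigError(f"sire {s} references unknown block {b}")
        for d, s in self.dams:
            if s not in sire_block:
                raise DesignConfigError(f"dam {d} references unknown sire {s}")
        seen = set()
        for ind, d, trt, sex in self.offspring:
            if ind in seen:
                raise DesignConfigError(f"duplicate individual id {ind}")
            seen.add(ind)
            if d not in dam_sire:
                raise DesignConfigError(f"offspring {ind} references unknown dam {d}")
            if trt not in TREATMENTS:
                raise DesignConfigError(f"unknown treatment {trt!r}")
            if sex not in SEXES:
                raise DesignConfigError(f"unknown sex {sex!r}")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_sires(self) -> int:
        return len(self.sires)

    @property
    def n_dams(self) -> int:
        return len(self.dams)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def to_frame(self) -> pd.DataFrame:
        """One row per offspring with full pedigree columns."""
        sire_block = dict(self.sires)
        dam_sire = dict(self.dams)
        rows = []
        for ind, dam, trt, sex in self.offspring:
            sire = dam_sire[dam]
            rows.append((ind, dam, sire, sire_block[sire], trt, sex))
        return pd.DataFrame(
            rows, columns=["individual", "dam", "sire", "block", "treatment", "sex"]
        )


def _allocate_counts(total, n_groups, low, high, rng):
    """Spread `total` over `n_groups` with each count in [low, high]."""
    if total is None:
        return rng.integers(low, high + 1, size=n_groups)
    if not (n_groups * low <= total <= n_groups * high):
        raise DesignConfigError(
            f"cannot place {total} units into {n_groups} groups with "
            f"per-group range [{low}, {high}]"
        )
    counts = np.full(n_groups, low, dtype=int)
    remaining = total - counts.sum()
    while remaining > 0:
        open_groups = np.flatnonzero(counts < high)
        g = rng.choice(open_groups)
        counts[g] += 1
        remaining -= 1
    return counts


def _normalize_spec(spec, n_groups, name):
    """Return (per-group list | None, low, high).

    An int means the same count in every group; a tuple ``(min, max)`` is a
    sampling range; a list gives explicit per-group counts.
    """
    if isinstance(spec, (int, np.integer)):
        if spec < 1:
            raise DesignConfigError(f"{name} must be >= 1")
        return [int(spec)] * n_groups, None, None
    if isinstance(spec, tuple) and len(spec) == 2:
        low, high = spec
        if low < 1 or high < low:
            raise DesignConfigError(f"invalid {name} range {spec}")
        return None, int(low), int(high)
    if isinstance(spec, list):
        if len(spec) != n_groups:
            raise DesignConfigError(
                f"{name} list has {len(spec)} entries for {n_groups} groups"
            )
        if min(spec) < 1:
            raise DesignConfigError(f"{name} entries must be >= 1")
        return [int(x) for x in spec], None, None
    raise DesignConfigError(f"cannot interpret {name}={spec!r}")


def build_pedigree(
    n_blocks: int,
    sires_per_block,
    dams_per_sire,
    offspring_per_dam_per_treatment: int = 6,
    seed: int = 0,
    *,
    total_sires: int | None = None,
    total_dams: int | None = None,
    females_per_dam_per_treatment: int | None = None,
    dropout: float = 0.0,
) -> BreedingDesign:
    """Generate a nested half-sib pedigree.

    Parameters
    ----------
    n_blocks : int
        Number of temporal mating blocks.
    sires_per_block : int or (min, max)
        Fixed count, or a sampling range; combine a range with
        ``total_sires`` to hit an exact overall sire count.
    dams_per_sire : int or (min, max)
        As above, optionally capped by ``total_dams``.
    offspring_per_dam_per_treatment : int
        Offspring tested per dam in *each* density treatment.
    females_per_dam_per_treatment : int, optional
        Sex split within each dam x treatment cell (default: as even as
        possible, females first).
    dropout : float
        Independent per-offspring removal probability emulating rearing
        mortality (default 0 = fully balanced design).
    seed : int
        Seed for all sampling; the same seed yields an identical design.
    """
    if n_blocks < 1 or offspring_per_dam_per_treatment < 1:
        raise DesignConfigError("counts must be >= 1")
    if not 0.0 <= dropout < 1.0:
        raise DesignConfigError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)

    per_block, lo, hi = _normalize_spec(sires_per_block, n_blocks, "sires_per_block")
    if per_block is None:
        sire_counts = _allocate_counts(total_sires, n_blocks, lo, hi, rng)
    else:
        sire_counts = np.asarray(per_block)

    blocks = [f"b{i + 1}" for i in range(n_blocks)]
    sires = []
    for b, cnt in zip(blocks, sire_counts):
        for _ in range(cnt):
            sires.append((f"s{len(sires) + 1}", b))

    n_sires = len(sires)
    per_sire, lo, hi = _normalize_spec(dams_per_sire, n_sires, "dams_per_sire")
    if per_sire is None:
        dam_counts = _allocate_counts(total_dams, n_sires, lo, hi, rng)
    else:
        dam_counts = np.asarray(per_sire)

    dams = []
    for (s, _), cnt in zip(sires, dam_counts):
        for _ in range(cnt):
            dams.append((f"d{len(dams) + 1}", s))

    k = offspring_per_dam_per_treatment
    nf = females_per_dam_per_treatment if females_per_dam_per_treatment is not None else (k + 1) // 2
    if not 0 <= nf <= k:
        raise DesignConfigError("females_per_dam_per_treatment out of range")

    offspring = []
    for d, _ in dams:
        for trt in TREATMENTS:
            for j in range(k):
                sex = "F" if j < nf else "M"
                offspring.append((f"i{len(offspring) + 1}", d, trt, sex))
    if dropout > 0.0:
        keep = rng.random(len(offspring)) >= dropout
        offspring = [o for o, kp in zip(offspring, keep) if kp]

    return BreedingDesign(blocks=blocks, sires=sires, dams=dams, offspring=offspring)


def paper_scale_design(seed: int = 0, dropout: float = 0.041) -> BreedingDesign:
    """The study-scale configuration: 7 blocks, 23 sires (2-6 per block),
    59 dams (2-3 per sire), 6 offspring per dam per density treatment
    (3F/3M), with light rearing attrition bringing ~708 offspring down to
    ~679."""
    return build_pedigree(
        n_blocks=7,
        sires_per_block=(2, 6),
        total_sires=23,
        dams_per_sire=(2, 3),
        total_dams=59,
        offspring_per_dam_per_treatment=6,
        females_per_dam_per_treatment=3,
        dropout=dropout,
        seed=seed,
    )
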