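"""Synthetic registered coils, planted weight models and censored datasets.

The generator reproduces the statistical shape the learning machinery
assumes: sequences over the position-specific residue alphabets typical of
leucine-zipper interfaces, an additive sparse ground-truth scoring model on
the log10(Kd/nM) scale, Gaussian measurement noise, right-censoring at a Kd
ceiling, and a binder/non-binder imbalance of roughly 20/80 achieved by
shifting the score offset.  The planted model always carries the family's
hallmark specificity element: favorable Asn-Asn and unfavorable
Asn-{Leu,Val,Ile} core a-a' pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import DEFAULT_CEILING_NM, Dataset, InteractionRecord
from .features import CATEGORIES, FeatureKey, encode
from .registers import AMINO_ACIDS, RegisteredCoil
from .semisvr import WeightModel

#: frequent native residues per interface position (85% occupancy in native
#: leucine zippers); b, c, f are drawn uniformly from all twenty
POSITION_ALPHABETS = {
    "a": "LNVIKART",
    "d": "LHVMI",
    "e": "EKRQL",
    "g": "EKRQL",
    "b": AMINO_ACIDS,
    "c": AMINO_ACIDS,
    "f": AMINO_ACIDS,
}


@dataclass
class SimulationConfig:
    n_proteins: int = 60
    blocks_per_protein: int = 6
    position_alphabets: dict = field(default_factory=lambda: dict(POSITION_ALPHABETS))
    off_alphabet_mass: float = 0.05  # chance of a non-frequent residue at a,d,e,g
    weight_support: int = 20  # planted non-zero weights
    pair_fraction: float = 0.9  # planted support drawn from pair categories
    weight_scale: float = 0.5
    noise_sd: float = 0.2
    ceiling: float = DEFAULT_CEILING_NM
    binder_fraction: float | None = 0.20
    heterodimer_density: float = 1.0  # fraction of hetero pairs measured (all-vs-all)
    seed: int = 0


def simulate_coils(config: SimulationConfig) -> list[RegisteredCoil]:
    """Draw iid registered sequences, f-phased, over the position alphabets."""
    rng = np.random.default_rng(config.seed)
    register = "fgabcde" * config.blocks_per_protein
    coils = []
    all_aa = list(AMINO_ACIDS)
    for i in range(config.n_proteins):
        residues = []
        for lab in register:
            alphabet = config.position_alphabets[lab]
            if (
                lab in "adeg"
                and config.off_alphabet_mass > 0
                and rng.random() < config.off_alphabet_mass
            ):
                pool = [aa for aa in all_aa if aa not in alphabet]
            else:
                pool = list(alphabet)
            residues.append(pool[rng.integers(len(pool))])
        coils.append(
            RegisteredCoil(id=f"P{i:03d}", residues="".join(residues), register=register)
        )
    return coils


def plant_model(config: SimulationConfig) -> WeightModel:
    """A sparse ground-truth weight vector over realizable feature keys.

    Most of the planted support sits on pair categories (``pair_fraction``),
    reflecting that pairwise core/flank contacts carry the bulk of coiled-coil
    specificity, with triplet terms a smaller correction.
    """
    from .features import PAIR_CATEGORIES, TRIPLET_CATEGORIES

    rng = np.random.default_rng(config.seed + 1)
    w: dict[FeatureKey, float] = {
        FeatureKey("a-a'", ("N", "N")): -0.8,
        FeatureKey("a-a'", ("L", "N")): +1.2,
        FeatureKey("a-a'", ("N", "V")): +1.2,
        FeatureKey("a-a'", ("I", "N")): +1.0,
    }
    pos_of = {  # position label per category element, to draw realizable residues
        cat: [el[1] for el in spec["elements"]] for cat, spec in CATEGORIES.items()
    }
    while len(w) < config.weight_support:
        cats = (
            PAIR_CATEGORIES
            if rng.random() < config.pair_fraction
            else TRIPLET_CATEGORIES
        )
        cat = cats[rng.integers(len(cats))]
        residues = tuple(
            config.position_alphabets[p][rng.integers(len(config.position_alphabets[p]))]
            for p in pos_of[cat]
        )
        key = FeatureKey(cat, residues)
        if key not in w:
            w[key] = float(rng.normal(0.0, config.weight_scale))
    return WeightModel(w=w, intercept=0.0)


def simulate_dataset(
    coils: list[RegisteredCoil],
    model: WeightModel,
    config: SimulationConfig,
) -> tuple[Dataset, WeightModel]:
    """Sample dimer measurements under the planted model.

    All homodimers are measured plus a random subset of heterodimers.  The
    noiseless score plus Gaussian noise gives log10 Kd; when a binder
    fraction is requested the score offset is shifted so that the requested
    fraction of measurements falls below the censoring ceiling (within 2%),
    and the same shift is recorded on the returned model's intercept.
    """
    rng = np.random.default_rng(config.seed + 2)
    pairs: list[tuple[str, str]] = [(c.id, c.id) for c in coils]
    ids = [c.id for c in coils]
    hetero = [
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    ]
    if config.heterodimer_density < 1.0 and hetero:
        m = int(round(config.heterodimer_density * len(hetero)))
        keep = rng.choice(len(hetero), size=m, replace=False)
        hetero = [hetero[i] for i in sorted(keep)]
    pairs.extend(hetero)

    by_id = {c.id: c for c in coils}
    scores = np.array(
        [model.predict(encode(by_id[a], by_id[b])) for a, b in pairs]
    )
    y = scores + rng.normal(0.0, config.noise_sd, size=len(pairs))

    shift = 0.0
    if config.binder_fraction is not None:
        # put the requested fraction of measurements under the ceiling
        shift = math.log10(config.ceiling) - float(
            np.quantile(y, config.binder_fraction)
        )
        y = y + shift
    kd = np.minimum(10.0**y, config.ceiling)
    kd = np.maximum(kd, 1e-3)  # guard against absurdly tight values

    records = [
        InteractionRecord(idA=min(a, b), idB=max(a, b), kd_nM=float(k), ceiling=config.ceiling)
        for (a, b), k in zip(pairs, kd)
    ]
    shifted = WeightModel(
        w=dict(model.w),
        C1=model.C1,
        C2=model.C2,
        epsilon=model.epsilon,
        E_cutoff=model.E_cutoff,
        intercept=model.intercept + shift,
    )
    return Dataset(coils=by_id, records=records, ceiling=config.ceiling), shifted


def simulate(config: SimulationConfig) -> tuple[Dataset, WeightModel]:
    """Coils + planted model + censored measurements, in one call."""
    coils = simulate_coils(config)
    model = plant_model(config)
    return simulate_dataset(coils, model, config)


def worked_toy() -> tuple[Dataset, WeightModel]:
    """A small deterministic dataset (12 proteins, ~40 pairs) used in docs
    and smoke tests; regenerating it always yields identical content."""
    config = SimulationConfig(
        n_proteins=12,
        blocks_per_protein=4,
        off_alphabet_mass=0.0,
        weight_support=20,
        noise_sd=0.1,
        heterodimer_density=0.45,
        seed=20150219,
    )
    return simulate(config)
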