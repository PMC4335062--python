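"""Dataset containers and file I/O.

Interaction measurements are dissociation constants (Kd, nM) for unordered
pairs of coiled coils, right-censored at a ceiling (default 5,000 nM): a
record at the ceiling means "no binding detected up to the ceiling", not a
measured affinity.  All modelling is done on the log10(Kd/nM) scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .registers import RegisteredCoil, assign_register

DEFAULT_CEILING_NM = 5000.0


@dataclass(frozen=True)
class InteractionRecord:
    """One dimer affinity measurement for the unordered pair {idA, idB}."""

    idA: str
    idB: str
    kd_nM: float
    ceiling: float = DEFAULT_CEILING_NM

    def __post_init__(self) -> None:
        if self.kd_nM <= 0:
            raise ValueError(f"non-positive Kd for pair ({self.idA},{self.idB}): {self.kd_nM}")
        if self.kd_nM > self.ceiling:
            object.__setattr__(self, "kd_nM", self.ceiling)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.idA, self.idB))

    @property
    def log10_kd(self) -> float:
        return math.log10(self.kd_nM)

    @property
    def is_binder(self) -> bool:
        return self.kd_nM < self.ceiling

    @property
    def is_censored(self) -> bool:
        return not self.is_binder


@dataclass
class Dataset:
    """Registered coils plus their pairwise affinity records."""

    coils: dict[str, RegisteredCoil]
    records: list[InteractionRecord]
    ceiling: float = DEFAULT_CEILING_NM

    def __post_init__(self) -> None:
        for rec in self.records:
            for cid in (rec.idA, rec.idB):
                if cid not in self.coils:
                    raise KeyError(f"record references unknown coil id {cid!r}")
        seen: set[frozenset[str]] = set()
        for rec in self.records:
            if rec.pair in seen:
                raise ValueError(f"duplicate unordered pair {set(rec.pair)}")
            seen.add(rec.pair)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_binders(self) -> int:
        return sum(r.is_binder for r in self.records)

    def protein_ids(self) -> list[str]:
        """Ids of coils that participate in at least one record, sorted."""
        used = set()
        for r in self.records:
            used.update((r.idA, r.idB))
        return sorted(used)

    def subset(self, keep: list[InteractionRecord]) -> "Dataset":
        return Dataset(coils=self.coils, records=list(keep), ceiling=self.ceiling)


def _collapse_duplicates(rows: list[tuple[str, str, float]]) -> dict[frozenset[str], float]:
    """Keep the minimum Kd per unordered pair (reciprocal-measurement rule)."""
    best: dict[frozenset[str], float] = {}
    for a, b, kd in rows:
        key = frozenset((a, b))
        if key not in best or kd < best[key]:
            best[key] = kd
    return best


def read_registers(path: str) -> dict[str, dict]:
    """Read a sidecar TSV with columns id, phase and optional species, parent."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns or "phase" not in df.columns:
        raise ValueError("register TSV needs 'id' and 'phase' columns")
    out = {}
    for _, row in df.iterrows():
        out[row["id"]] = {
            "phase": row["phase"],
            "species": row.get("species") if isinstance(row.get("species"), str) else None,
            "parent": row.get("parent") if isinstance(row.get("parent"), str) else None,
        }
    return out


def read_dataset(
    interactions_path: str,
    sequences_path: str,
    register_spec: str | dict | int,
    ceiling: float = DEFAULT_CEILING_NM,
    columns: tuple[str, str, str] | tuple[int, int, int] = (0, 1, 2),
) -> Dataset:
    """Ingest an interaction CSV plus registered FASTA sequences.

    ``register_spec`` is either a path to a sidecar TSV (id, phase[, species,
    parent]), a dict of the same shape, or a single phase applied to every
    sequence.  ``columns`` selects the two identifier columns and the Kd
    column of the CSV by name or position.
    """
    df = pd.read_csv(interactions_path)
    cols = [df.columns[c] if isinstance(c, int) else c for c in columns]
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"interactions CSV has no column {c!r}")

    if isinstance(register_spec, str):
        registers = read_registers(register_spec)
    elif isinstance(register_spec, dict):
        registers = register_spec
    else:
        registers = None  # single phase for all

    coils: dict[str, RegisteredCoil] = {}
    for rec in SeqIO.parse(sequences_path, "fasta"):
        if registers is None:
            info = {"phase": register_spec, "species": None, "parent": None}
        else:
            if rec.id not in registers:
                raise KeyError(f"no register entry for sequence {rec.id!r}")
            info = registers[rec.id]
        coils[rec.id] = assign_register(
            rec.id,
            str(rec.seq).upper(),
            info["phase"],
            species=info.get("species"),
            parent=info.get("parent"),
        )

    rows = []
    for _, row in df.iterrows():
        a, b, kd = str(row[cols[0]]), str(row[cols[1]]), float(row[cols[2]])
        for cid in (a, b):
            if cid not in coils:
                raise KeyError(f"interaction references id {cid!r} missing from FASTA")
        if kd <= 0:
            raise ValueError(f"non-positive Kd for pair ({a},{b}): {kd}")
        rows.append((a, b, kd))

    records = [
        InteractionRecord(idA=min(pair), idB=max(pair), kd_nM=kd, ceiling=ceiling)
        for pair, kd in sorted(
            _collapse_duplicates(rows).items(), key=lambda kv: tuple(sorted(kv[0]))
        )
    ]
    return Dataset(coils=coils, records=records, ceiling=ceiling)


# -- WeightModel JSON round-trip ---------------------------------------------


def write_model(model, path: str) -> None:
    """Serialize a WeightModel to JSON with full float precision."""
    from .features import CATEGORIES  # local import avoids a cycle

    for key in model.w:
        if key.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {key.category!r}")
    payload = {
        "weights": {str(k): w for k, w in model.w.items()},
        "C1": model.C1,
        "C2": model.C2,
        "epsilon": model.epsilon,
        "E_cutoff": model.E_cutoff,
        "intercept": model.intercept,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path: str):
    from .features import FeatureKey
    from .semisvr import WeightModel

    with open(path) as fh:
        payload = json.load(fh)
    w = {FeatureKey.parse(s): float(v) for s, v in payload["weights"].items()}
    return WeightModel(
        w=w,
        C1=payload["C1"],
        C2=payload["C2"],
        epsilon=payload["epsilon"],
        E_cutoff=payload["E_cutoff"],
        intercept=payload.get("intercept", 0.0),
    )
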