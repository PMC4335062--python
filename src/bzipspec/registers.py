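"""Heptad-register bookkeeping for coiled-coil sequences.

A coiled coil repeats a seven-residue pattern whose positions are labelled
``a``–``g``; ``a`` and ``d`` form the hydrophobic core, ``e`` and ``g`` flank
it.  Two coordinate frames are used throughout the package:

* the *canonical a-frame*: heptad ``i`` spans positions ``a_i``..``g_i`` and
  cross-heptad contacts such as ``g_i``–``e'_{i+1}`` are indexed in it;
* the *f-anchored block frame* used for design: a block is a seven-residue
  window in ``(f, g, a, b, c, d, e)`` order, so block ``k`` holds ``f_k,
  g_k`` of a-frame heptad ``k`` and ``a``..``e`` of heptad ``k+1``.

Residue indices are 0-based internally; heptad and block indices are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HEPTAD = "abcdefg"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: heptad positions that line the dimer interface
CORE_POSITIONS = "adeg"


def _next_label(label: str) -> str:
    return HEPTAD[(HEPTAD.index(label) + 1) % 7]


@dataclass(frozen=True)
class RegisteredCoil:
    """A coiled-coil sequence with a per-residue heptad register.

    Parameters
    ----------
    id : str
        Unique identifier.
    residues : str
        Amino-acid sequence (one-letter codes).
    register : str
        Per-residue heptad labels; must cycle ``...f,g,a,b,c...`` without
        gaps and have the same length as ``residues``.
    species : str, optional
    parent : str, optional
        Identifier of the parent protein when this coil is a length variant.
    """

    id: str
    residues: str
    register: str
    species: str | None = None
    parent: str | None = None
    # caches, computed in __post_init__
    heptad_of: tuple[int, ...] = field(init=False, repr=False, compare=False)
    blocks: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.register):
            raise ValueError(
                f"coil {self.id!r}: register length {len(self.register)} != "
                f"sequence length {len(self.residues)}"
            )
        if not self.residues:
            raise ValueError(f"coil {self.id!r}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"coil {self.id!r}: non-standard residues {sorted(bad)}")
        for i in range(1, len(self.register)):
            if self.register[i] != _next_label(self.register[i - 1]):
                raise ValueError(
                    f"coil {self.id!r}: register breaks the heptad cycle at "
                    f"residue {i + 1} ({self.register[i - 1]!r} -> {self.register[i]!r})"
                )
        # a-frame heptad index per residue: heptad 1 starts at the first
        # residue; a new heptad starts at every subsequent 'a'.
        hept = []
        h = 1
        for i, lab in enumerate(self.register):
            if i > 0 and lab == "a":
                h += 1
            hept.append(h)
        object.__setattr__(self, "heptad_of", tuple(hept))
        # f-anchored blocks: start indices of complete 7-residue windows
        # beginning at an 'f', non-overlapping from the first 'f'.
        starts = []
        pos = self.register.find("f")
        if pos >= 0:
            while pos + 7 <= len(self.residues):
                starts.append(pos)
                pos += 7
        object.__setattr__(self, "blocks", tuple(starts))

    # -- a-frame coordinates -------------------------------------------------
    def coord_index(self) -> dict[tuple[int, str], int]:
        """Map (heptad index, position label) -> residue index."""
        return {
            (h, lab): i
            for i, (h, lab) in enumerate(zip(self.heptad_of, self.register))
        }

    def heptad_range(self) -> tuple[int, int]:
        """First and last (possibly partial) a-frame heptad index."""
        return self.heptad_of[0], self.heptad_of[-1]

    # -- f-frame blocks ------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_seq(self, k: int) -> str:
        """Residues of 1-based block ``k`` in (f,g,a,b,c,d,e) order."""
        s = self.blocks[k - 1]
        return self.residues[s : s + 7]

    def block_of_index(self, i: int) -> int | None:
        """1-based block containing residue index ``i``, or None."""
        for k, s in enumerate(self.blocks, start=1):
            if s <= i < s + 7:
                return k
        return None

    def unblocked_indices(self) -> list[int]:
        """Residue indices not covered by any complete f-anchored block."""
        covered = set()
        for s in self.blocks:
            covered.update(range(s, s + 7))
        return [i for i in range(len(self.residues)) if i not in covered]

    def block_subcoil(self, first: int, n: int, new_id: str | None = None) -> "RegisteredCoil":
        """Sub-coil covering blocks ``first``..``first+n-1`` (1-based)."""
        if first < 1 or first + n - 1 > self.n_blocks:
            raise ValueError(
                f"coil {self.id!r}: blocks {first}..{first + n - 1} out of "
                f"range (has {self.n_blocks})"
            )
        s = self.blocks[first - 1]
        e = self.blocks[first + n - 2] + 7
        return RegisteredCoil(
            id=new_id or f"{self.id}[{first}:{first + n - 1}]",
            residues=self.residues[s:e],
            register=self.register[s:e],
            species=self.species,
            parent=self.parent or self.id,
        )

    def core_residues(self) -> str:
        """Residues at a, d, e, g positions, in sequence order."""
        return "".join(
            r for r, lab in zip(self.residues, self.register) if lab in CORE_POSITIONS
        )


def assign_register(
    seq_id: str,
    sequence: str,
    phase: int | str,
    species: str | None = None,
    parent: str | None = None,
) -> RegisteredCoil:
    """Label a sequence with a cyclic heptad register starting at ``phase``.

    ``phase`` is the heptad position of the first residue, given either as a
    letter in ``a``–``g`` or as its 0-based index into ``abcdefg``.
    """
    if len(sequence) < 7:
        raise ValueError(f"coil {seq_id!r}: need at least 7 residues, got {len(sequence)}")
    if isinstance(phase, str):
        if phase not in HEPTAD:
            raise ValueError(f"phase must be one of {HEPTAD!r}, got {phase!r}")
        p = HEPTAD.index(phase)
    else:
        p = int(phase)
        if not 0 <= p <= 6:
            raise ValueError(f"phase index must be in 0..6, got {p}")
    register = "".join(HEPTAD[(p + i) % 7] for i in range(len(sequence)))
    return RegisteredCoil(
        id=seq_id, residues=sequence, register=register, species=species, parent=parent
    )
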