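"""Screening verdicts: rank candidates by affinity and adhesion vs. a reference.

Affinity is the inverse of the equilibrium dissociation constant, so the
affinity ranking is ascending in K_D (rank 1 = smallest K_D = tightest
binder); the adhesion ranking is descending in rupture force (rank 1 =
strongest).  A candidate "beats" the reference ligand only under strict
inequality on the respective axis -- equality is not a win.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "MoleculeRecord",
    "ScreeningTable",
    "rank_by_affinity",
    "rank_by_adhesion",
    "compare_to_reference",
]


@dataclass
class MoleculeRecord:
    name: str
    kD: float  # M
    adhesion_force: float  # pN
    affinity_rank: int  # 1 = smallest K_D
    adhesion_rank: int  # 1 = largest force
    beats_reference_affinity: bool
    beats_reference_adhesion: bool


@dataclass
class ScreeningTable:
    """Joined screening result; ``tied`` flags any exact tie on either axis."""

    records: list[MoleculeRecord]
    reference: str
    tied: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "molecule": r.name,
                    "kD_M": r.kD,
                    "adhesion_pN": r.adhesion_force,
                    "affinity_rank": r.affinity_rank,
                    "adhesion_rank": r.adhesion_rank,
                    "beats_reference_affinity": r.beats_reference_affinity,
                    "beats_reference_adhesion": r.beats_reference_adhesion,
                }
                for r in self.records
            ]
        )

    def summary(self) -> str:
        lines = [f"Screening summary (reference: {self.reference})"]
        for r in sorted(self.records, key=lambda r: r.affinity_rank):
            verdict = []
            if r.name != self.reference:
                verdict.append(
                    "beats reference affinity"
                    if r.beats_reference_affinity
                    else "does not beat reference affinity"
                )
                verdict.append(
                    "beats reference adhesion"
                    if r.beats_reference_adhesion
                    else "does not beat reference adhesion"
                )
            lines.append(
                f"  {r.name}: K_D = {r.kD:.3g} M (affinity rank {r.affinity_rank}), "
                f"adhesion = {r.adhesion_force:.2f} pN (rank {r.adhesion_rank})"
                + (f" -- {', '.join(verdict)}" if verdict else " -- reference")
            )
        if self.tied:
            lines.append("  note: exact ties present; tie order is lexicographic")
        return "\n".join(lines)


def _check_nonempty(mapping: dict, what: str) -> None:
    if not mapping:
        raise InvalidInputError(f"empty {what} map")


def rank_by_affinity(kd_by_molecule: dict[str, float]) -> tuple[list[str], bool]:
    """Order molecules by ascending K_D (highest affinity first).

    Ties break lexicographically; the second return value flags whether any
    tie occurred.
    """
    _check_nonempty(kd_by_molecule, "K_D")
    for name, kd in kd_by_molecule.items():
        if not (kd > 0):
            raise InvalidInputError(f"K_D for {name} must be > 0, got {kd}")
    ordered = sorted(kd_by_molecule, key=lambda n: (kd_by_molecule[n], n))
    values = sorted(kd_by_molecule.values())
    tied = any(a == b for a, b in zip(values, values[1:]))
    return ordered, tied


def rank_by_adhesion(force_by_molecule: dict[str, float]) -> tuple[list[str], bool]:
    """Order molecules by descending adhesion force (strongest first)."""
    _check_nonempty(force_by_molecule, "adhesion force")
    for name, f in force_by_molecule.items():
        if not (f >= 0):
            raise InvalidInputError(f"adhesion force for {name} must be >= 0, got {f}")
    ordered = sorted(force_by_molecule, key=lambda n: (-force_by_molecule[n], n))
    values = sorted(force_by_molecule.values())
    tied = any(a == b for a, b in zip(values, values[1:]))
    return ordered, tied


def compare_to_reference(
    kd_by_molecule: dict[str, float],
    force_by_molecule: dict[str, float],
    reference: str,
) -> ScreeningTable:
    """Build the joined screening table against a reference ligand.

    Every molecule must have both a K_D and an adhesion force; the reference
    is compared to itself with both flags False.
    """
    if set(kd_by_molecule) != set(force_by_molecule):
        raise InvalidInputError(
            "K_D and adhesion maps must cover the same molecules; "
            f"difference: {set(kd_by_molecule) ^ set(force_by_molecule)}"
        )
    if reference not in kd_by_molecule:
        raise InvalidInputError(f"reference {reference!r} missing from the inputs")
    aff_order, tied_a = rank_by_affinity(kd_by_molecule)
    adh_order, tied_f = rank_by_adhesion(force_by_molecule)
    kd_ref = kd_by_molecule[reference]
    f_ref = force_by_molecule[reference]
    records = [
        MoleculeRecord(
            name=name,
            kD=kd_by_molecule[name],
            adhesion_force=force_by_molecule[name],
            affinity_rank=aff_order.index(name) + 1,
            adhesion_rank=adh_order.index(name) + 1,
            beats_reference_affinity=kd_by_molecule[name] < kd_ref,
            beats_reference_adhesion=force_by_molecule[name] > f_ref,
        )
        for name in kd_by_molecule
    ]
    records.sort(key=lambda r: r.affinity_rank)
    return ScreeningTable(records=records, reference=reference, tied=tied_a or tied_f)
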