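"""Peptide/protein bookkeeping: digestion factors, yields, AQUA levels.

The link between a protein concentration ``y_p`` and the concentration of
one of its tryptic peptides ``i`` is ``H_i(y) = sum_p g_ip d_ip y_p`` where
``d_ip`` counts the copies of peptide ``i`` released per molecule of
protein ``p`` under complete digestion and ``g_ip`` in (0, 1] corrects for
incomplete digestion.  The matrix formulation handles non-proteotypic
peptides shared by several proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["PeptideProteinMap", "MappingError"]


class MappingError(ValueError):
    """Raised when the digestion-factor map does not cover the data."""


@dataclass(frozen=True)
class PeptideProteinMap:
    """Digestion factors d_ip, yields g_ip and AQUA concentrations kappa*_i.

    Parameters
    ----------
    peptides, proteins
        Row and column labels of the matrices.
    d
        (S, P) matrix of non-negative integer digestion factors; every
        peptide row must have at least one nonzero entry.
    g
        (S, P) matrix of digestion yields in (0, 1]; entries where d is
        zero are ignored.
    kappa_star
        (S,) spiked AQUA peptide concentrations (same amount units as y).
    """

    peptides: tuple[str, ...]
    proteins: tuple[str, ...]
    d: np.ndarray
    g: np.ndarray
    kappa_star: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        g = np.asarray(self.g, dtype=float)
        ks = np.asarray(self.kappa_star, dtype=float)
        S, P = len(self.peptides), len(self.proteins)
        if d.shape != (S, P) or g.shape != (S, P) or ks.shape != (S,):
            raise MappingError(
                f"inconsistent shapes: d {d.shape}, g {g.shape}, "
                f"kappa_star {ks.shape} for {S} peptides x {P} proteins"
            )
        if np.any(d < 0) or np.any(d != np.round(d)):
            raise MappingError("digestion factors d_ip must be non-negative integers")
        if not np.all(d.sum(axis=1) >= 1):
            orphan = self.peptides[int(np.argmax(d.sum(axis=1) < 1))]
            raise MappingError(f"peptide {orphan!r} maps to no protein (all d_ip = 0)")
        active = d > 0
        if np.any((g[active] <= 0) | (g[active] > 1)):
            raise MappingError("digestion yields g_ip must lie in (0, 1]")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "kappa_star", ks)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def h(self, y: np.ndarray) -> np.ndarray:
        """Expected peptide concentrations H_i(y) = sum_p g_ip d_ip y_p."""
        return (self.g * self.d) @ np.asarray(y, dtype=float)

    def with_yields(self, g: np.ndarray) -> "PeptideProteinMap":
        """Return a copy with the yield matrix replaced."""
        return replace(self, g=np.asarray(g, dtype=float))

    def peptides_of(self, protein: str) -> list[str]:
        p = self.proteins.index(protein)
        return [pep for i, pep in enumerate(self.peptides) if self.d[i, p] > 0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per nonzero (peptide, protein) pair."""
        rows = []
        for i, pep in enumerate(self.peptides):
            for p, prot in enumerate(self.proteins):
                if self.d[i, p] > 0:
                    rows.append(
                        {
                            "peptide": pep,
                            "protein": prot,
                            "d": int(self.d[i, p]),
                            "g": float(self.g[i, p]),
                            "kappa_star": float(self.kappa_star[i]),
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeptideProteinMap":
        required = {"peptide", "protein", "d", "g", "kappa_star"}
        missing = required - set(frame.columns)
        if missing:
            raise MappingError(f"map table missing columns: {sorted(missing)}")
        peptides = tuple(dict.fromkeys(frame["peptide"]))
        proteins = tuple(dict.fromkeys(frame["protein"]))
        S, P = len(peptides), len(proteins)
        d = np.zeros((S, P))
        g = np.ones((S, P))
        ks = np.zeros(S)
        for _, row in frame.iterrows():
            i = peptides.index(row["peptide"])
            p = proteins.index(row["protein"])
            d[i, p] = row["d"]
            g[i, p] = row["g"]
            ks[i] = row["kappa_star"]
        return cls(peptides, proteins, d, g, ks)
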