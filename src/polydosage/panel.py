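"""Genotype panels and relative subgenome dosage.

A serial allopolyploid design combines two parental subgenomes (here called
A and C, after the *Brassica rapa* and *B. oleracea* chromosome sets) in a
range of copy-number combinations.  The default panel holds the two diploid
parents (AA, CC), the F1 hybrid (AC), the allotetraploid (CCAA) and the two
reciprocal allotriploids (AAC, CCA).

The quantity everything downstream correlates against is the *relative
dosage* of a subgenome in a genotype: its copy number divided by the total
genome-copy complement.  For subgenome A over the series
(AA, AAC, AC, CCAA, CCA) this is exactly (1, 2/3, 1/2, 1/2, 1/3); the series
for subgenome C is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Tuple

import pandas as pd

#: The two parental subgenome labels.
SUBGENOMES: Tuple[str, str] = ("A", "C")

#: (name, copies of A, copies of C) for the default six-genotype panel.
DEFAULT_ENTRIES: Tuple[Tuple[str, int, int], ...] = (
    ("AA", 2, 0),
    ("CC", 0, 2),
    ("AC", 1, 1),
    ("AAC", 2, 1),
    ("CCA", 1, 2),
    ("CCAA", 2, 2),
)


@dataclass(frozen=True)
class GenotypePanel:
    """An ordered set of genotypes with per-subgenome copy numbers.

    Parameters
    ----------
    entries
        Tuples of ``(genotype_name, copies_of_A, copies_of_C)``.  Names must
        be unique, copy numbers non-negative integers, and every genotype
        must carry at least one genome copy.
    """

    entries: Tuple[Tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("genotype names must be unique")
        for name, a, c in self.entries:
            if not (isinstance(a, int) and isinstance(c, int)):
                raise TypeError(f"copy numbers of {name!r} must be integers")
            if a < 0 or c < 0:
                raise ValueError(f"copy numbers of {name!r} must be >= 0")
            if a + c < 1:
                raise ValueError(f"genotype {name!r} has no genome copies")

    @property
    def names(self) -> List[str]:
        return [name for name, _, _ in self.entries]

    def copies(self, genotype: str) -> Tuple[int, int]:
        """Return ``(copies_of_A, copies_of_C)`` for a genotype."""
        for name, a, c in self.entries:
            if name == genotype:
                return a, c
        raise KeyError(f"unknown genotype {genotype!r}")

    def has_subgenome(self, genotype: str, subgenome: str) -> bool:
        a, c = self.copies(genotype)
        _check_subgenome(subgenome)
        return (a if subgenome == "A" else c) > 0


def _check_subgenome(subgenome: str) -> None:
    if subgenome not in SUBGENOMES:
        raise KeyError(f"unknown subgenome {subgenome!r}; expected one of {SUBGENOMES}")


def build_genotype_panel() -> GenotypePanel:
    """Return the default six-genotype panel AA, CC, AC, AAC, CCA, CCAA."""
    return GenotypePanel(DEFAULT_ENTRIES)


def relative_dosage(panel: GenotypePanel, genotype: str, subgenome: str) -> float:
    """Copies of ``subgenome`` over total genome copies, as an exact fraction.

    Examples
    --------
    In the default panel the A subgenome occupies 2/3 of AAC and 1/2 of CCAA;
    it is absent (dosage 0) in CC.
    """
    _check_subgenome(subgenome)
    a, c = panel.copies(genotype)
    num = a if subgenome == "A" else c
    return float(Fraction(num, a + c))


def carrier_genotypes(panel: GenotypePanel, subgenome: str) -> List[str]:
    """Genotypes carrying at least one copy of ``subgenome``, by descending dosage.

    Ties are broken by panel order, which for the default panel yields the
    series (AA, AAC, AC, CCAA, CCA) for A and (CC, CCA, AC, CCAA, AAC) for C.
    """
    _check_subgenome(subgenome)
    carriers = [g for g in panel.names if panel.has_subgenome(g, subgenome)]
    order = {g: i for i, g in enumerate(panel.names)}
    carriers.sort(key=lambda g: (-relative_dosage(panel, g, subgenome), order[g]))
    return carriers


def dosage_vector(panel: GenotypePanel, subgenome: str) -> pd.Series:
    """Relative dosage of ``subgenome`` across its carrier genotypes.

    Returns a Series indexed by genotype in descending-dosage order, e.g.
    (1, 2/3, 1/2, 1/2, 1/3) over (AA, AAC, AC, CCAA, CCA) for subgenome A.
    """
    carriers = carrier_genotypes(panel, subgenome)
    return pd.Series(
        [relative_dosage(panel, g, subgenome) for g in carriers],
        index=pd.Index(carriers, name="genotype"),
        name=f"dosage_{subgenome}",
    )
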