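"""Pedigree structure for a three-generation (P / F1 / F2) design.

The analysis follows gamete transmissions from the two F1 parents to the
F2 offspring.  Each transmission has a *side*: ``paternal`` for the gamete
contributed by the F1 father, ``maternal`` for the F1 mother.  Phasing a
side requires five individuals: the F1 parent, its own two parents (the
grandparents of that side), the F1 partner, and the offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PATERNAL = "paternal"
MATERNAL = "maternal"
SIDES = (PATERNAL, MATERNAL)

MALE = "male"
FEMALE = "female"


@dataclass(frozen=True)
class SideRoles:
    """The five samples needed to phase one transmission side."""

    f1: str
    grandfather: str
    grandmother: str
    partner: str
    offspring: tuple[str, ...]


@dataclass
class Pedigree:
    """An 11-individual three-generation pedigree.

    Parameters
    ----------
    father, mother : str
        Sample names of the two F1 parents.
    paternal_grandfather, paternal_grandmother : str
        Parents of the F1 father.
    maternal_grandfather, maternal_grandmother : str
        Parents of the F1 mother.
    offspring : tuple of str
        Sample names of the F2 individuals.
    sex : dict
        Sample name -> ``"male"`` | ``"female"``.  Sex matters on the Z
        chromosome, where females are hemizygous outside the
        pseudoautosomal region.
    """

    father: str
    mother: str
    paternal_grandfather: str
    paternal_grandmother: str
    maternal_grandfather: str
    maternal_grandmother: str
    offspring: tuple[str, ...]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offspring = tuple(self.offspring)
        for name in self.samples:
            if name not in self.sex:
                raise ValueError(f"sex missing for sample {name!r}")
            if self.sex[name] not in (MALE, FEMALE):
                raise ValueError(f"unknown sex label {self.sex[name]!r} for {name!r}")
        for name, want in [
            (self.father, MALE),
            (self.mother, FEMALE),
            (self.paternal_grandfather, MALE),
            (self.paternal_grandmother, FEMALE),
            (self.maternal_grandfather, MALE),
            (self.maternal_grandmother, FEMALE),
        ]:
            if self.sex[name] != want:
                raise ValueError(f"sample {name!r} must be {want} for its role")

    @property
    def founders(self) -> tuple[str, str, str, str]:
        return (
            self.paternal_grandfather,
            self.paternal_grandmother,
            self.maternal_grandfather,
            self.maternal_grandmother,
        )

    @property
    def samples(self) -> list[str]:
        """All samples, founders first, then F1, then F2."""
        return [*self.founders, self.father, self.mother, *self.offspring]

    def is_female(self, name: str) -> bool:
        return self.sex[name] == FEMALE

    @property
    def females(self) -> list[str]:
        return [s for s in self.samples if self.is_female(s)]

    @property
    def males(self) -> list[str]:
        return [s for s in self.samples if not self.is_female(s)]

    def side_roles(self, side: str) -> SideRoles:
        if side == PATERNAL:
            return SideRoles(
                f1=self.father,
                grandfather=self.paternal_grandfather,
                grandmother=self.paternal_grandmother,
                partner=self.mother,
                offspring=self.offspring,
            )
        if side == MATERNAL:
            return SideRoles(
                f1=self.mother,
                grandfather=self.maternal_grandfather,
                grandmother=self.maternal_grandmother,
                partner=self.father,
                offspring=self.offspring,
            )
        raise ValueError(f"unknown side {side!r}")

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) triples for Mendelian checks."""
        out = [
            (self.father, self.paternal_grandfather, self.paternal_grandmother),
            (self.mother, self.maternal_grandfather, self.maternal_grandmother),
        ]
        out.extend((child, self.father, self.mother) for child in self.offspring)
        return out

    def to_frame(self) -> pd.DataFrame:
        parents = {self.father: (self.paternal_grandfather, self.paternal_grandmother),
                   self.mother: (self.maternal_grandfather, self.maternal_grandmother)}
        for child in self.offspring:
            parents[child] = (self.father, self.mother)
        rows = []
        for name in self.samples:
            fa, mo = parents.get(name, ("0", "0"))
            rows.append({"sample": name, "father": fa, "mother": mo,
                         "sex": self.sex[name]})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        df = df.astype(str)
        sex = dict(zip(df["sample"], df["sex"]))
        founders = df[(df["father"] == "0") & (df["mother"] == "0")]["sample"].tolist()
        non_founders = df[(df["father"] != "0")]
        f1 = non_founders[non_founders["father"].isin(founders)]
        f2 = non_founders[~non_founders["father"].isin(founders)]
        if len(founders) != 4 or len(f1) != 2 or len(f2) < 1:
            raise ValueError("pedigree is not a 4 + 2 + n three-generation design")
        father = f1[f1["sample"].map(sex) == MALE]["sample"].item()
        mother = f1[f1["sample"].map(sex) == FEMALE]["sample"].item()
        frow = f1[f1["sample"] == father].iloc[0]
        mrow = f1[f1["sample"] == mother].iloc[0]
        return cls(
            father=father,
            mother=mother,
            paternal_grandfather=frow["father"],
            paternal_grandmother=frow["mother"],
            maternal_grandfather=mrow["father"],
            maternal_grandmother=mrow["mother"],
            offspring=tuple(f2["sample"]),
            sex=sex,
        )

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_pedigree(n_offspring: int = 5) -> Pedigree:
    """The 4 + 2 + 5 design with one female F2 (the rest male)."""
    offspring = tuple(f"F2_{i}" for i in range(1, n_offspring + 1))
    sex = {
        "PGF": MALE, "PGM": FEMALE, "MGF": MALE, "MGM": FEMALE,
        "father": MALE, "mother": FEMALE,
    }
    for i, name in enumerate(offspring):
        sex[name] = FEMALE if i == 0 else MALE
    return Pedigree(
        father="father",
        mother="mother",
        paternal_grandfather="PGF",
        paternal_grandmother="PGM",
        maternal_grandfather="MGF",
        maternal_grandmother="MGM",
        offspring=offspring,
        sex=sex,
    )
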