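"""Lipid shorthand parsing and structural metrics.

Lipid species are annotated with shorthand names such as ``"PC 36:2"``
(sum composition: total acyl carbons and double bonds) or, when chain-level
information is available, ``"PC 16:0/20:5"``. This module parses those names
into :class:`LipidSpecies` records, classifies acyl saturation (SFA / MUFA /
PUFA), and computes the intensity-weighted mean carbon number per fatty acid
used in homeoviscous-adaptation analyses.

Class-level attributes (phosphorus content, chloroplast association, betaine
lipids) come from an editable ontology table shipped with the package; the
defaults follow the standard marine glycerolipid classes (the chloroplast
lipids are SQDG, MGDG, DGDG and PG; the betaine lipids DGTS/A and DGCC).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotationError, DegenerateDataError, FeatureTable

#: classes whose glycerolipids carry two acyl chains unless stated otherwise
_TRIACYL_CLASSES = {"TAG"}

_NAME_RE = re.compile(r"^(?P<cls>[A-Za-z0-9/\-]+(?:\s[A-Za-z]+)?)\s+(?P<comp>\d+:\d+(?:/\d+:\d+)*)$")


def load_class_ontology(path: Optional[str] = None) -> pd.DataFrame:
    """Load the headgroup-class ontology (shipped default or a user TSV)."""
    if path is None:
        ref = resources.files("eigenlipid.data").joinpath("class_ontology.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    table = table.set_index("class")
    for col in ("has_phosphorus", "is_chloroplast", "is_betaine"):
        table[col] = table[col].astype(bool)
    return table


_DEFAULT_ONTOLOGY = load_class_ontology()

#: chloroplast-associated classes under the default ontology
CHLOROPLAST_CLASSES = tuple(_DEFAULT_ONTOLOGY.index[_DEFAULT_ONTOLOGY["is_chloroplast"]])

#: membrane glycerolipid classes used for chain-length ~ temperature analysis
MEMBRANE_GLYCEROLIPID_CLASSES = (
    "PC", "PG", "PE", "SQDG", "MGDG", "DGDG", "GADG", "DGTS/A", "DGCC",
)


@dataclass
class LipidSpecies:
    """Parsed structural identity of one annotated lipid."""

    id: str
    name: str
    headgroup: str
    total_carbons: int
    total_double_bonds: int
    n_chains: int
    chains: Optional[list[tuple[int, int]]] = None
    annotation_tier: str = "Ann.1"
    has_phosphorus: bool = False
    is_chloroplast: bool = False
    is_betaine: bool = False

    def __post_init__(self) -> None:
        if self.total_carbons < self.n_chains * 2:
            raise AnnotationError(
                f"{self.name}: {self.total_carbons} carbons impossible for {self.n_chains} chains"
            )
        if self.chains is not None:
            c = sum(x[0] for x in self.chains)
            d = sum(x[1] for x in self.chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise AnnotationError(f"{self.name}: chain sums {c}:{d} do not match totals")

    @property
    def carbons_per_chain(self) -> float:
        return self.total_carbons / self.n_chains

    def format_name(self) -> str:
        if self.chains is not None:
            comp = "/".join(f"{c}:{d}" for c, d in self.chains)
        else:
            comp = f"{self.total_carbons}:{self.total_double_bonds}"
        return f"{self.headgroup} {comp}"


@dataclass
class SaturationClass:
    """Per-chain saturation calls and the species-level class."""

    chain_classes: Optional[list[str]]  # "SFA" / "MUFA" / "PUFA" per chain
    species_class: str  # "SFA/MUFA" or "PUFA-containing"
    heuristic: bool = False  # True when decided from sum composition only


def _classify_chain(double_bonds: int) -> str:
    if double_bonds == 0:
        return "SFA"
    if double_bonds == 1:
        return "MUFA"
    return "PUFA"


def parse_lipid_name(
    name: str,
    species_id: Optional[str] = None,
    annotation_tier: str = "Ann.1",
    chains: Optional[str] = None,
    ontology: Optional[pd.DataFrame] = None,
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    ``chains`` optionally supplies chain-level composition as a string like
    ``"16:0/20:5"`` for names given at the sum-composition level.
    """
    if ontology is None:
        ontology = _DEFAULT_ONTOLOGY
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise AnnotationError(f"cannot parse lipid name {name!r}")
    cls = m.group("cls")
    comp = m.group("comp")
    parts = comp.split("/")
    chain_list: Optional[list[tuple[int, int]]]
    if len(parts) > 1:
        chain_list = [tuple(int(v) for v in p.split(":")) for p in parts]  # type: ignore[misc]
        total_c = sum(c for c, _ in chain_list)
        total_d = sum(d for _, d in chain_list)
        n_chains = len(chain_list)
    else:
        total_c, total_d = (int(v) for v in parts[0].split(":"))
        n_chains = 3 if cls in _TRIACYL_CLASSES else 2
        chain_list = None
        if chains:
            chain_list = [tuple(int(v) for v in p.split(":")) for p in chains.split("/")]  # type: ignore[misc]
            n_chains = len(chain_list)
    if cls in ontology.index:
        row = ontology.loc[cls]
        has_p, chloro, betaine = bool(row["has_phosphorus"]), bool(row["is_chloroplast"]), bool(row["is_betaine"])
    else:
        has_p = chloro = betaine = False
    return LipidSpecies(
        id=species_id or name,
        name=name,
        headgroup=cls,
        total_carbons=total_c,
        total_double_bonds=total_d,
        n_chains=n_chains,
        chains=chain_list,
        annotation_tier=annotation_tier,
        has_phosphorus=has_p,
        is_chloroplast=chloro,
        is_betaine=betaine,
    )


def parse_annotation_table(annotations: pd.DataFrame, ontology: Optional[pd.DataFrame] = None) -> dict[str, LipidSpecies]:
    """Parse a feature annotation table (columns: name, annotation_tier, chains)."""
    species: dict[str, LipidSpecies] = {}
    for fid, row in annotations.iterrows():
        chains = row.get("chains")
        if isinstance(chains, float) and np.isnan(chains):
            chains = None
        species[str(fid)] = parse_lipid_name(
            row["name"],
            species_id=str(fid),
            annotation_tier=str(row.get("annotation_tier", "Ann.1")),
            chains=chains,
            ontology=ontology,
        )
    return species


def classify_saturation(species: LipidSpecies) -> SaturationClass:
    """Classify a species as SFA/MUFA or PUFA-containing.

    With chain-level data the call is exact: PUFA-containing iff any chain
    carries ≥ 2 double bonds. For sum compositions the minimal-assumption
    heuristic is used: PUFA-containing iff total double bonds exceed the
    chain count (otherwise the double bonds could be spread ≤ 1 per chain);
    such calls are flagged ``heuristic``.
    """
    if species.chains is not None:
        per_chain = [_classify_chain(d) for _, d in species.chains]
        cls = "PUFA-containing" if "PUFA" in per_chain else "SFA/MUFA"
        return SaturationClass(chain_classes=per_chain, species_class=cls, heuristic=False)
    cls = "PUFA-containing" if species.total_double_bonds > species.n_chains else "SFA/MUFA"
    return SaturationClass(chain_classes=None, species_class=cls, heuristic=True)


def contains_epa(species: LipidSpecies) -> bool:
    """True if the species carries a 20:5 (eicosapentaenoic acid) chain."""
    if species.chains is None:
        return False
    return any((c, d) == (20, 5) for c, d in species.chains)


def select_species(
    species: dict[str, LipidSpecies],
    headgroups: Optional[Sequence[str]] = None,
    saturation: Optional[str] = None,
) -> list[str]:
    """Feature ids matching a headgroup set and/or a saturation class.

    ``saturation`` is ``"SFA"``/``"SFA/MUFA"`` (species without any PUFA
    chain) or ``"PUFA"``/``"PUFA-containing"``.
    """
    if saturation in ("SFA", "MUFA"):
        saturation = "SFA/MUFA"
    if saturation == "PUFA":
        saturation = "PUFA-containing"
    out = []
    for fid, sp in species.items():
        if headgroups is not None and sp.headgroup not in headgroups:
            continue
        if saturation is not None and classify_saturation(sp).species_class != saturation:
            continue
        out.append(fid)
    return out


def weighted_mean_chain_length(
    features: FeatureTable,
    species: dict[str, LipidSpecies],
    feature_ids: Sequence[str],
) -> pd.Series:
    """Per-sample intensity-weighted mean carbon number per fatty acid.

    For the selected species, Σ_i I_i · (C_i / n_chains_i) / Σ_i I_i per
    sample; samples where the selection has zero total intensity come back
    as missing.
    """
    feature_ids = [f for f in feature_ids if f in features.data.index]
    if not feature_ids:
        raise DegenerateDataError("empty species selection for weighted mean chain length")
    sub = features.data.loc[feature_ids]
    cpf = np.array([species[f].carbons_per_chain for f in feature_ids])
    total = sub.sum(axis=0)
    weighted = sub.mul(cpf, axis=0).sum(axis=0)
    out = weighted / total
    out[total <= 0] = np.nan
    out.name = "mean_chain_length"
    return out
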