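"""Drug-likeness library preparation: descriptors, filter cascade, dedup, exact masses.

The cascade reproduces a conservative library-preparation recipe for screening
a protein-protein interface: eight physico-chemical bounds (molecular weight
< 450 Da; cLogP and Solubility Forecast Index between -3 and 1; topological
polar surface area < 110 Å²; 0-5 H-bond donors and acceptors; 0-6 rotatable
bonds; net formal charge between -1 and 1), plus removal of duplicates, PAINS
matches and reactive/warhead chemotypes.  The SFI is cLogP plus the aromatic
ring count.  Note the SFI window mirrors the cLogP window here and is far
narrower than the usual SFI < 5 solubility rule; both are configurable.

Descriptor conventions (all standard RDKit choices): Crippen cLogP, Ertl TPSA,
Lipinski-style donor (N/O-H) and acceptor (N+O) counts, strict rotatable-bond
count (terminal and amide C-N bonds excluded), average-isotope molecular
weight.  Exact (monoisotopic) masses are a separate utility for high-resolution
MS arithmetic and play no part in the filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from math import inf
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .errors import FormulaError, LibraryError

__all__ = [
    "Molecule",
    "DescriptorSet",
    "Bound",
    "FilterPolicy",
    "FilterAudit",
    "parse_library",
    "descriptors",
    "monoisotopic_mass",
    "parse_formula",
    "dedup",
    "apply_filters",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")  # record-level problems are reported via our own log


@dataclass
class Molecule:
    """A library member: RDKit graph plus its source record id."""

    id: str
    mol: Chem.Mol
    source: str = ""

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class DescriptorSet:
    """The eight filterable properties (plus the aromatic ring count behind SFI)."""

    mw: float
    clogp: float
    n_aromatic_rings: int
    sfi: float
    tpsa: float
    hbd: int
    hba: int
    rotb: int
    net_charge: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mw": self.mw, "clogp": self.clogp, "n_aromatic_rings": self.n_aromatic_rings,
            "sfi": self.sfi, "tpsa": self.tpsa, "hbd": self.hbd, "hba": self.hba,
            "rotb": self.rotb, "net_charge": self.net_charge,
        }


@dataclass(frozen=True)
class Bound:
    """An interval bound on one descriptor; each end open or closed."""

    lo: float = -inf
    hi: float = inf
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def holds(self, value: float) -> bool:
        above = value >= self.lo if self.lo_inclusive else value > self.lo
        below = value <= self.hi if self.hi_inclusive else value < self.hi
        return above and below

    def describe(self, name: str) -> str:
        parts = []
        if self.lo != -inf:
            parts.append(f"{name} {'>=' if self.lo_inclusive else '>'} {self.lo:g}")
        if self.hi != inf:
            parts.append(f"{name} {'<=' if self.hi_inclusive else '<'} {self.hi:g}")
        return " and ".join(parts) if parts else f"{name} unbounded"


def _default_bounds() -> dict[str, Bound]:
    # strict "<" where the recipe prints "<" (mw, tpsa); closed "between" elsewhere
    return {
        "mw": Bound(hi=450.0, hi_inclusive=False),
        "clogp": Bound(-3.0, 1.0),
        "sfi": Bound(-3.0, 1.0),
        "tpsa": Bound(hi=110.0, hi_inclusive=False),
        "hbd": Bound(0, 5),
        "hba": Bound(0, 5),
        "rotb": Bound(0, 6),
        "net_charge": Bound(-1, 1),
    }


def _pains_catalog() -> FilterCatalog:
    params = FilterCatalogParams()
    params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)  # A + B + C
    return FilterCatalog(params)


def _load_reactive_patterns(path: str | Path | None) -> dict[str, Chem.Mol]:
    if path is None:
        text = resources.files("clampscreen").joinpath("data/reactive_patterns.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)["patterns"]
    out = {}
    for name, smarts in raw.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LibraryError(f"bad reactive SMARTS for {name!r}")
        out[name] = patt
    return out


@dataclass
class FilterPolicy:
    """Descriptor bounds plus PAINS and reactive substructure screens."""

    bounds: dict[str, Bound] = field(default_factory=_default_bounds)
    use_pains: bool = True
    reactive_patterns: dict[str, Chem.Mol] = field(default_factory=lambda: _load_reactive_patterns(None))
    _pains: FilterCatalog | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.use_pains and self._pains is None:
            self._pains = _pains_catalog()

    @classmethod
    def from_files(cls, reactive_json: str | Path | None = None, use_pains: bool = True,
                   bounds: dict[str, Bound] | None = None) -> "FilterPolicy":
        return cls(
            bounds=bounds or _default_bounds(),
            use_pains=use_pains,
            reactive_patterns=_load_reactive_patterns(reactive_json),
        )

    def violations(self, mol: Molecule, desc: DescriptorSet | None = None) -> list[str]:
        """All violated rules (never just the first)."""
        desc = desc or descriptors(mol)
        values = desc.as_dict()
        out = [name for name, bound in self.bounds.items() if not bound.holds(values[name])]
        if self.use_pains and self._pains is not None and self._pains.HasMatch(mol.mol):
            out.append("pains")
        for name, patt in self.reactive_patterns.items():
            if mol.mol.HasSubstructMatch(patt):
                out.append(f"reactive:{name}")
        return out


@dataclass
class FilterAudit:
    """Per-molecule verdicts and per-rule rejection totals."""

    results: list[dict] = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.results if r["pass"])

    @property
    def n_total(self) -> int:
        return len(self.results)

    def rule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.results:
            for rule in r["violated_rules"]:
                counts[rule] = counts.get(rule, 0) + 1
        return counts

    def passing_ids(self) -> list[str]:
        return [r["id"] for r in self.results if r["pass"]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"id": r["id"], "pass": r["pass"],
                   "violated_rules": ";".join(r["violated_rules"])}
            row.update(r["descriptors"])
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"n_total": self.n_total, "n_pass": self.n_pass,
                "rule_rejections": self.rule_counts()}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_library(path: str | Path) -> list[Molecule]:
    """Read a SMILES (.smi: ``SMILES<TAB>id``) or SDF v2000 library.

    Unparsable records are logged and skipped; a library with zero parsable
    records raises :class:`LibraryError`.
    """
    path = Path(path)
    molecules: list[Molecule] = []
    n_skipped = 0
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("skipping unparsable SDF record %d of %s", i + 1, path.name)
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record_{i + 1}"
            molecules.append(Molecule(mid, mol, source=f"{path.name}:{i + 1}"))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mid = parts[1].strip() if len(parts) > 1 else f"record_{lineno}"
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    n_skipped += 1
                    logger.warning("skipping unparsable SMILES at %s:%d", path.name, lineno)
                    continue
                molecules.append(Molecule(mid, mol, source=f"{path.name}:{lineno}"))
    if not molecules:
        raise LibraryError(f"no parsable records in {path}")
    if n_skipped:
        logger.info("%s: parsed %d molecules, skipped %d", path.name, len(molecules), n_skipped)
    return molecules


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def descriptors(mol: Molecule | Chem.Mol) -> DescriptorSet:
    """The eight filterable properties of one molecule."""
    m = mol.mol if isinstance(mol, Molecule) else mol
    clogp = Crippen.MolLogP(m)
    n_ar = rdMolDescriptors.CalcNumAromaticRings(m)
    return DescriptorSet(
        mw=Descriptors.MolWt(m),
        clogp=clogp,
        n_aromatic_rings=n_ar,
        sfi=clogp + n_ar,
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(m),
        hba=rdMolDescriptors.CalcNumLipinskiHBA(m),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(m),
        net_charge=Chem.GetFormalCharge(m),
    )


# ---------------------------------------------------------------------------
# exact masses
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = r"([A-Z][a-z]?)(\d*)"


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C25H37N4O9`` into an element->count map."""
    import re

    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(_FORMULA_TOKEN, formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic mass (Da): sum of most-abundant-isotope masses.

    Matches high-resolution MS ``calcd`` arithmetic for a printed ion formula,
    e.g. ``C25H37N4O9`` (an [M+H]+ formula already including the proton)
    gives 537.2561 at 4-decimal reporting.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    pt = Chem.GetPeriodicTable()
    total = 0.0
    for element, count in formula.items():
        if count < 0:
            raise FormulaError(f"negative count for {element}")
        try:
            mass = pt.GetMostCommonIsotopeMass(element)
        except Exception:
            raise FormulaError(f"unknown element symbol {element!r}") from None
        if mass <= 0 and element != "X":
            raise FormulaError(f"unknown element symbol {element!r}")
        total += count * mass
    return total


# ---------------------------------------------------------------------------
# dedup and the cascade
# ---------------------------------------------------------------------------

def dedup(library: list[Molecule]) -> tuple[list[Molecule], dict[str, str]]:
    """Remove duplicates by canonical structure; first occurrence wins.

    Returns ``(unique, duplicate_map)`` where the map sends each dropped id to
    the id it duplicates.  Tautomer-insensitive matching is out of scope.
    """
    seen: dict[str, str] = {}
    unique: list[Molecule] = []
    duplicates: dict[str, str] = {}
    for mol in library:
        key = mol.canonical_smiles()
        if key in seen:
            duplicates[mol.id] = seen[key]
        else:
            seen[key] = mol.id
            unique.append(mol)
    return unique, duplicates


def apply_filters(library: list[Molecule], policy: FilterPolicy | None = None) -> FilterAudit:
    """Run the full cascade; a molecule passes iff it violates no rule.

    The audit records *every* violated rule per molecule, so rule application
    order cannot influence totals.
    """
    policy = policy or FilterPolicy()
    audit = FilterAudit()
    for mol in library:
        desc = descriptors(mol)
        violated = policy.violations(mol, desc)
        audit.results.append({
            "id": mol.id,
            "pass": not violated,
            "violated_rules": violated,
            "descriptors": desc.as_dict(),
        })
    return audit
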