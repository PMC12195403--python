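"""Curated metabolic gene panels with cofactor, pathway, domain and compartment annotations.

A :class:`GeneModel` is the ordered, validated gene panel that every
downstream stage (divergence metrics, anomaly scoring, stratified reports)
is restricted to.  Annotations use closed vocabularies so that stratified
views (by metabolic domain, cofactor dependency or subcellular compartment)
are well defined; free-text cofactor notations from curation sources are
normalized through a synonym map at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "GeneAnnotation",
    "GeneModel",
    "GeneModelError",
    "COFACTOR_VOCAB",
    "DOMAIN_VOCAB",
    "COMPARTMENT_VOCAB",
    "normalize_cofactor",
    "load_gene_model",
    "write_gene_model",
    "subset",
    "bundled_panel",
]


class GeneModelError(ValueError):
    """Raised when a gene panel violates its schema or vocabularies."""


#: Controlled cofactor-dependency tags.  ``none`` marks genes whose product
#: has no annotated small-molecule cofactor (e.g. carriers).
COFACTOR_VOCAB = frozenset(
    {
        "thiamine_TPP",
        "biotin",
        "lipoic_acid",
        "pantothenate_CoA",
        "PLP_B6",
        "NAD",
        "FAD",
        "ATP",
        "GDP",
        "Mg2plus",
        "molybdenum",
        "heme",
        "B12",
        "none",
    }
)

#: The three metabolic domains used for stratification, plus a catch-all.
DOMAIN_VOCAB = frozenset(
    {"glycolysis_ppp", "redox_sulfur_one_carbon", "mitochondrial", "other"}
)

COMPARTMENT_VOCAB = frozenset({"cytosolic", "mitochondrial", "both", "unknown"})

# Free-text synonyms (lower-cased) -> controlled tag.  Curation tables mix
# vitamin shorthand ("B1"), chemical names and nucleotide forms; ADP/ATP are
# collapsed to the adenine-nucleotide tag, NADH variants to NAD.
_COFACTOR_SYNONYMS = {
    "b1": "thiamine_TPP",
    "vitamin b1": "thiamine_TPP",
    "thiamine": "thiamine_TPP",
    "tpp": "thiamine_TPP",
    "thiamine pyrophosphate": "thiamine_TPP",
    "b7": "biotin",
    "vitamin b7": "biotin",
    "lipoate": "lipoic_acid",
    "lipoic acid": "lipoic_acid",
    "la": "lipoic_acid",
    "coa": "pantothenate_CoA",
    "pantothenate": "pantothenate_CoA",
    "pantothenic acid": "pantothenate_CoA",
    "b5": "pantothenate_CoA",
    "vitamin b5": "pantothenate_CoA",
    "plp": "PLP_B6",
    "b6": "PLP_B6",
    "vitamin b6": "PLP_B6",
    "plp (vitamin b6)": "PLP_B6",
    "pyridoxal phosphate": "PLP_B6",
    "nad+": "NAD",
    "nadh": "NAD",
    "nadh+": "NAD",
    "adp": "ATP",
    "mg2+": "Mg2plus",
    "mg": "Mg2plus",
    "magnesium": "Mg2plus",
    "moco": "molybdenum",
    "cytochrome b5": "heme",
    "vitamin b12": "B12",
    "cobalamin": "B12",
    "": "none",
}

# case-insensitive exact tag lookup
_CANONICAL = {tag.lower(): tag for tag in COFACTOR_VOCAB}

_TSV_COLUMNS = [
    "symbol",
    "enzyme_name",
    "domain",
    "pathway",
    "cofactors",
    "compartment",
    "functional_role",
]


def normalize_cofactor(token: str) -> str:
    """Map a free-text cofactor token to its controlled-vocabulary tag.

    Matching is case-insensitive; unknown tokens raise
    :class:`GeneModelError` naming the offending string.
    """
    key = token.strip().lower()
    if key in _CANONICAL:
        return _CANONICAL[key]
    if key in _COFACTOR_SYNONYMS:
        return _COFACTOR_SYNONYMS[key]
    raise GeneModelError(f"unknown cofactor token: {token!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """One panel gene with its enzyme, pathway and dependency annotations."""

    symbol: str
    enzyme_name: str
    domain: str
    pathway: str
    cofactors: frozenset[str]
    compartment: str
    functional_role: str

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise GeneModelError("gene symbol must be nonempty")
        if self.domain not in DOMAIN_VOCAB:
            raise GeneModelError(
                f"{self.symbol}: unknown domain {self.domain!r} "
                f"(expected one of {sorted(DOMAIN_VOCAB)})"
            )
        if self.compartment not in COMPARTMENT_VOCAB:
            raise GeneModelError(
                f"{self.symbol}: unknown compartment {self.compartment!r}"
            )
        if not self.cofactors:
            object.__setattr__(self, "cofactors", frozenset({"none"}))
        bad = set(self.cofactors) - COFACTOR_VOCAB
        if bad:
            raise GeneModelError(
                f"{self.symbol}: unknown cofactor tag(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """An ordered, validated collection of :class:`GeneAnnotation`."""

    annotations: tuple[GeneAnnotation, ...]
    name: str = "panel"
    version: str = "1"

    def __post_init__(self) -> None:
        # Loaded panels must be nonempty (enforced in load_gene_model);
        # empty models are permitted as subset() results.
        seen: set[str] = set()
        for ann in self.annotations:
            if ann.symbol in seen:
                raise GeneModelError(f"duplicate gene symbol: {ann.symbol}")
            seen.add(ann.symbol)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self.annotations)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    @property
    def _by_symbol(self) -> dict[str, GeneAnnotation]:
        return {a.symbol: a for a in self.annotations}

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.annotations]

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in model {self.name!r}") from None

    def subset(
        self,
        by_domain: Optional[str] = None,
        by_cofactor: Optional[str] = None,
        by_compartment: Optional[str] = None,
    ) -> "GeneModel":
        return subset(self, by_domain, by_cofactor, by_compartment)


def _parse_row(row: dict[str, str], lineno: int) -> GeneAnnotation:
    raw_cof = row["cofactors"].strip()
    tokens = [t for t in raw_cof.split(";")] if raw_cof else [""]
    try:
        cofactors = frozenset(normalize_cofactor(t) for t in tokens)
        return GeneAnnotation(
            symbol=row["symbol"].strip(),
            enzyme_name=row["enzyme_name"].strip(),
            domain=row["domain"].strip(),
            pathway=row["pathway"].strip(),
            cofactors=cofactors,
            compartment=row["compartment"].strip(),
            functional_role=row["functional_role"].strip(),
        )
    except GeneModelError as exc:
        raise GeneModelError(f"line {lineno}: {exc}") from None


def load_gene_model(path: str | Path, name: str | None = None, version: str = "1") -> GeneModel:
    """Load a gene panel from an annotation TSV.

    The file must be UTF-8, tab-delimited, with header columns
    ``symbol  enzyme_name  domain  pathway  cofactors  compartment
    functional_role``; the cofactors cell is semicolon-separated and may be
    empty (interpreted as ``none``).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header != _TSV_COLUMNS:
            raise GeneModelError(
                f"bad header in {path.name}: expected {_TSV_COLUMNS}, got {header}"
            )
        annotations = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_TSV_COLUMNS):
                raise GeneModelError(
                    f"line {lineno}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            annotations.append(_parse_row(dict(zip(_TSV_COLUMNS, fields)), lineno))
    if not annotations:
        raise GeneModelError(f"{path.name}: gene model file contains no genes")
    return GeneModel(tuple(annotations), name=name or path.stem, version=version)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Serialize a panel back to the annotation-TSV schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for a in model:
            cof = ";".join(sorted(a.cofactors))
            fh.write(
                "\t".join(
                    [
                        a.symbol,
                        a.enzyme_name,
                        a.domain,
                        a.pathway,
                        cof,
                        a.compartment,
                        a.functional_role,
                    ]
                )
                + "\n"
            )


def _check_filter(value: Optional[str], vocab: frozenset[str], what: str) -> None:
    if value is not None and value not in vocab:
        raise GeneModelError(f"unknown {what} filter: {value!r}")


def subset(
    model: GeneModel,
    by_domain: Optional[str] = None,
    by_cofactor: Optional[str] = None,
    by_compartment: Optional[str] = None,
) -> GeneModel:
    """Filter a panel by domain, cofactor and/or compartment (AND semantics).

    Order is preserved; the result may be empty.  Unknown filter tokens
    raise :class:`GeneModelError`.
    """
    _check_filter(by_domain, DOMAIN_VOCAB, "domain")
    _check_filter(by_cofactor, COFACTOR_VOCAB, "cofactor")
    _check_filter(by_compartment, COMPARTMENT_VOCAB, "compartment")
    keep = tuple(
        a
        for a in model
        if (by_domain is None or a.domain == by_domain)
        and (by_cofactor is None or by_cofactor in a.cofactors)
        and (by_compartment is None or a.compartment == by_compartment)
    )
    return GeneModel(keep, name=model.name, version=model.version)


def bundled_panel() -> GeneModel:
    """The packaged 26-gene metabolic panel used as the default fixture.

    Covers TCA-cycle, transamination, one-carbon, sulfur and energy-buffering
    enzymes plus the vitamin/cofactor transporters (SLC5A6, SLC19A2/3) and
    pantothenate kinases.  Real analyses supply their own, larger panel.
    """
    from importlib import resources

    path = resources.files("pm3.data").joinpath("core_panel.tsv")
    with resources.as_file(path) as p:
        return load_gene_model(p, name="core_panel", version="1")
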