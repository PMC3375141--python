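"""Gene-symbol canonicalization and family-based generalization.

Named-entity recognizers frequently include context words around the core
gene symbol ("human Esr-1 subunit") and surfaces vary in hyphenation and
case.  Canonicalization strips superfluous affix tokens from both ends,
drops non-alphanumeric characters and lowercases, so that minor lexical
variants of one symbol collapse ("human Esr-1 subunit" -> "esr1").

A :class:`FamilyScheme` then maps canonical symbols many-to-one onto gene
family identifiers (HomoloGene-like or Ensembl-like tables supplied as
TSV), letting events aggregate across species and synonyms.  A mention's
*generalization key* is its canonical symbol under the canonical scheme, or
its family id under a family scheme (falling back to the canonical symbol
when unmapped, so unmapped symbols keep singleton identity).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .model import Document, GeneMention

_NON_ALNUM = re.compile(r"[^a-z0-9]+")

#: Seed affix tokens: species adjectives and structural words that NER
#: systems attach around the core symbol.
DEFAULT_PREFIXES = frozenset(
    {"human", "murine", "mouse", "rat", "yeast", "bovine", "porcine", "mammalian", "the"}
)
DEFAULT_SUFFIXES = frozenset(
    {"protein", "proteins", "gene", "genes", "subunit", "promoter", "mrna", "homolog"}
)


@dataclass(frozen=True)
class AffixLexicon:
    """Lowercase affix tokens stripped from mention surfaces."""

    prefixes: frozenset[str] = DEFAULT_PREFIXES
    suffixes: frozenset[str] = DEFAULT_SUFFIXES

    def __post_init__(self):
        for tok in list(self.prefixes) + list(self.suffixes):
            if not tok or tok != tok.lower():
                raise ValueError(f"affix tokens must be non-empty and lowercase: {tok!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AffixLexicon":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(
            prefixes=frozenset(data.get("prefixes", [])),
            suffixes=frozenset(data.get("suffixes", [])),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"prefixes": sorted(self.prefixes), "suffixes": sorted(self.suffixes)}
            ),
            encoding="utf-8",
        )


def canonicalize(surface: str, lex: Optional[AffixLexicon] = None) -> str:
    """Reduce a mention surface to its canonical gene symbol.

    Whitespace tokens found in the affix lexicon are stripped iteratively
    from both ends; the remainder is lowercased and stripped of
    non-alphanumeric characters (non-ASCII letters such as Greek are
    dropped, not transliterated: "NF-κB" -> "nfb").  If affix stripping
    consumes the whole surface the rule falls back to the lowercased
    alphanumeric content of the original.  Returns "" for surfaces with no
    alphanumeric content at all (uncanonicalizable; such mentions are
    excluded from generalization).
    """
    if lex is None:
        lex = AffixLexicon()
    tokens = surface.split()
    changed = True
    while tokens and changed:
        changed = False
        if tokens and tokens[0].lower() in lex.prefixes:
            tokens = tokens[1:]
            changed = True
        if tokens and tokens[-1].lower() in lex.suffixes:
            tokens = tokens[:-1]
            changed = True
    core = _NON_ALNUM.sub("", " ".join(tokens).lower())
    if not core:
        core = _NON_ALNUM.sub("", surface.lower())
    return core


@dataclass
class FamilyScheme:
    """A many-to-one mapping from canonical gene symbols to family ids."""

    name: str
    mapping: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    @classmethod
    def from_tsv(cls, path: Union[str, Path], name: Optional[str] = None) -> "FamilyScheme":
        """Load ``canonical<TAB>family_id`` rows.

        A symbol listed under several families is resolved to the family
        with the most members in the table, ties broken by lexicographic
        family id.
        """
        path = Path(path)
        pairs: list[tuple[str, str]] = []
        for line_no, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 TSV fields")
            sym, fam = parts[0].strip(), parts[1].strip()
            if not re.fullmatch(r"[a-z0-9]+", sym):
                raise ValueError(f"{path}:{line_no}: symbol {sym!r} is not canonical")
            pairs.append((sym, fam))
        sizes = Counter(f for _, f in pairs)
        mapping: dict[str, str] = {}
        for sym, fam in pairs:
            if sym not in mapping:
                mapping[sym] = fam
            else:
                best = min((mapping[sym], fam), key=lambda f: (-sizes[f], f))
                mapping[sym] = best
        return cls(name=name or path.stem, mapping=mapping, provenance=str(path))

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = [f"{sym}\t{fam}" for sym, fam in sorted(self.mapping.items())]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def assign_family(canonical: str, scheme: FamilyScheme) -> str:
    """Family id for a canonical symbol, or "unmapped"."""
    return scheme.mapping.get(canonical, "unmapped")


def generalization_key(
    mention: GeneMention, scheme: Union[str, FamilyScheme] = "canonical"
) -> str:
    """The aggregation key of a mention under a generalization scheme.

    Under ``"canonical"`` this is the canonical symbol; under a family
    scheme it is the family id, falling back to the canonical symbol for
    unmapped symbols.  Raises :class:`ValueError` for an unknown scheme
    name and for mentions whose canonical form has not been filled.
    """
    if not mention.canonical:
        raise ValueError(f"mention {mention.mention_id} has no canonical form")
    if isinstance(scheme, str):
        if scheme == "canonical":
            return mention.canonical
        fam = mention.family_keys.get(scheme)
        if fam is None:
            raise ValueError(f"unknown generalization scheme {scheme!r}")
    else:
        fam = mention.family_keys.get(scheme.name) or assign_family(mention.canonical, scheme)
    return mention.canonical if fam == "unmapped" else fam


def canonicalize_corpus(
    docs: Iterable[Document],
    lex: Optional[AffixLexicon] = None,
    schemes: Iterable[FamilyScheme] = (),
) -> None:
    """Fill ``canonical`` and ``family_keys`` on every mention, in place."""
    schemes = list(schemes)
    for doc in docs:
        for m in doc.mentions:
            m.canonical = canonicalize(m.surface, lex)
            if m.canonical:
                for sc in schemes:
                    m.family_keys[sc.name] = assign_family(m.canonical, sc)


def coverage_stats(docs: Iterable[Document], schemes: Iterable[FamilyScheme]) -> pd.DataFrame:
    """Symbol-coverage table per generalization scheme.

    For each scheme: how many distinct canonical symbols (and what share of
    occurrences) resolve to a family.  The canonical row covers everything
    by construction.  Uncanonicalizable mentions are excluded.
    """
    occ = Counter()
    for doc in docs:
        for m in doc.mentions:
            if m.canonical:
                occ[m.canonical] += 1
    n_distinct = len(occ)
    n_occ = sum(occ.values())
    rows = [
        {
            "scheme": "canonical",
            "distinct_mapped": n_distinct,
            "distinct_pct": 100.0 if n_distinct else 0.0,
            "occurrences_mapped": n_occ,
            "occurrence_pct": 100.0 if n_occ else 0.0,
        }
    ]
    for sc in schemes:
        mapped = {s for s in occ if s in sc.mapping}
        occ_mapped = sum(occ[s] for s in mapped)
        rows.append(
            {
                "scheme": sc.name,
                "distinct_mapped": len(mapped),
                "distinct_pct": 100.0 * len(mapped) / n_distinct if n_distinct else 0.0,
                "occurrences_mapped": occ_mapped,
                "occurrence_pct": 100.0 * occ_mapped / n_occ if n_occ else 0.0,
            }
        )
    return pd.DataFrame(rows)
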