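"""Link clinotype names to genes through local geneset (GMT) files.

Clinotype names carry assay qualifiers that have no biological meaning
("Basophils Percentage", "Monocytes Absolute value").  The normalization
rule removes such stop terms and singularizes the remaining tokens, so
"Basophils Percentage" → "Basophil" and "Monocytes Absolute value" →
"Monocyte".  The query term is then matched case-insensitively as a
substring against geneset names, yielding (clinotype, gene) links with
their source geneset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import Geneset

#: Non-biological qualifiers removed from clinotype names.  Multi-word
#: terms are matched first; matching is case-insensitive and whole-word.
DEFAULT_STOP_TERMS = (
    "absolute value",
    "percentage",
    "ratio",
    "volume",
    "count",
    "concentration",
    "width",
    "mean",
    "distributed",
)

#: Irregular singular forms that plain 's'-stripping would mangle.
DEFAULT_SINGULAR_EXCEPTIONS = {
    "glucose": "glucose",
    "erythrocytes": "erythrocyte",
    "leukocytes": "leukocyte",
    "species": "species",
    "diabetes": "diabetes",
}


@dataclass(frozen=True)
class NameNormalizationConfig:
    stop_terms: tuple[str, ...] = DEFAULT_STOP_TERMS
    singularization_exceptions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SINGULAR_EXCEPTIONS)
    )


class UnmappableNameError(ValueError):
    """Nothing remains of a clinotype name after stop-term removal."""


def _singularize(token: str, exceptions: Mapping[str, str]) -> str:
    low = token.lower()
    if low in exceptions:
        target = exceptions[low]
        # preserve original capitalization of the leading character
        return token[: len(target)] if low.startswith(target) else target
    if len(token) > 3 and low.endswith("s") and not low.endswith("ss"):
        return token[:-1]
    return token


def normalize_clinotype_name(
    name: str, config: NameNormalizationConfig = NameNormalizationConfig()
) -> str:
    """Strip stop terms and singularize; idempotent.

    Raises :class:`UnmappableNameError` when nothing remains.
    """
    if not name or not name.strip():
        raise UnmappableNameError("empty clinotype name")
    text = " ".join(name.split())
    lowered = text.lower()
    for term in sorted(config.stop_terms, key=len, reverse=True):
        term_l = term.lower()
        tokens = lowered.split(" ")
        term_tokens = term_l.split(" ")
        out_tokens: list[str] = []
        orig_tokens = text.split(" ")
        i = 0
        while i < len(tokens):
            if tokens[i : i + len(term_tokens)] == term_tokens:
                i += len(term_tokens)
            else:
                out_tokens.append(orig_tokens[i])
                i += 1
        text = " ".join(out_tokens)
        lowered = text.lower()
    if not text:
        raise UnmappableNameError(f"clinotype name {name!r} is unmappable after stripping")
    tokens = [
        _singularize(tok, config.singularization_exceptions) for tok in text.split(" ")
    ]
    return " ".join(tokens)


@dataclass(frozen=True)
class ClinotypeGeneLink:
    clinotype: str
    query_term: str
    gene: str
    geneset: str


@dataclass
class GeneLinkResult:
    links: list[ClinotypeGeneLink]
    unmatched: list[str]  # query terms with no matching geneset
    unmappable: list[str]  # clinotype names empty after stripping

    def unique_pairs(self) -> set[tuple[str, str]]:
        """Deduplicated (clinotype, gene) pairs across source genesets."""
        return {(link.clinotype, link.gene) for link in self.links}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clinotype": [l.clinotype for l in self.links],
                "query_term": [l.query_term for l in self.links],
                "gene": [l.gene for l in self.links],
                "geneset": [l.geneset for l in self.links],
            }
        )


def map_to_genesets(
    clinotypes: Iterable[str],
    genesets: Sequence[Geneset],
    config: NameNormalizationConfig = NameNormalizationConfig(),
) -> GeneLinkResult:
    """Match normalized clinotype query terms against geneset names.

    Matching is a case-insensitive substring test of the query term
    (spaces also tried as underscores) against the geneset name.  Output
    is sorted, hence independent of geneset file ordering.
    """
    links: list[ClinotypeGeneLink] = []
    unmatched: list[str] = []
    unmappable: list[str] = []
    for clinotype in clinotypes:
        try:
            term = normalize_clinotype_name(clinotype, config)
        except UnmappableNameError:
            unmappable.append(clinotype)
            continue
        needles = {term.lower(), term.lower().replace(" ", "_")}
        hit = False
        for gs in genesets:
            hay = gs.name.lower()
            if any(needle in hay for needle in needles):
                hit = True
                links.extend(
                    ClinotypeGeneLink(clinotype, term, gene, gs.name) for gene in gs.genes
                )
        if not hit:
            unmatched.append(term)
    links = sorted(set(links), key=lambda l: (l.clinotype, l.geneset, l.gene))
    return GeneLinkResult(links=links, unmatched=sorted(set(unmatched)), unmappable=unmappable)
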