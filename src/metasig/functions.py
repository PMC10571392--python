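"""Genome-centric functional configuration.

KEGG-style module definitions are boolean step expressions over KO
identifiers: space-separated top-level blocks are sequential steps, commas
separate alternatives (OR), '+' joins members of a protein complex (AND),
'-'-prefixed components are optional and ignored, and parentheses nest
arbitrarily.  Module completeness of a genome is the fraction of steps its
KO set satisfies; a module is complete when every step is satisfied.

Occurrence and completeness contrasts compare the presence of a function
(or the completeness of a module) between case-enriched and control-enriched
species sets with the two-sided Fisher exact test, FDR-adjusted across
functions.  Biosynthesis capabilities (SCFAs, secondary bile acids, uremic
toxin precursors) are flagged by the presence of key marker synthetases from
an editable, versioned rule table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ValidationError
from .signatures import CASE_ENRICHED, CONTROL_ENRICHED, NONE, q_values


class ModuleParseError(ValueError):
    """Malformed module definition; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class KOLeaf:
    id: str

    def evaluate(self, ko_set) -> bool:
        return self.id in ko_set

    def serialize(self) -> str:
        return self.id


@dataclass(frozen=True)
class AndExpr:
    terms: tuple
    complex: bool = False  # '+'-joined complex vs space-joined group

    def evaluate(self, ko_set) -> bool:
        return all(t.evaluate(ko_set) for t in self.terms)

    def serialize(self) -> str:
        sep = "+" if self.complex else " "
        return sep.join(
            f"({t.serialize()})" if isinstance(t, OrExpr) else t.serialize()
            for t in self.terms
        )


@dataclass(frozen=True)
class OrExpr:
    terms: tuple

    def evaluate(self, ko_set) -> bool:
        return any(t.evaluate(ko_set) for t in self.terms)

    def serialize(self) -> str:
        return ",".join(
            f"({t.serialize()})"
            if isinstance(t, AndExpr) and not t.complex
            else t.serialize()
            for t in self.terms
        )


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    steps: tuple

    def serialize(self) -> str:
        out = []
        for s in self.steps:
            text = s.serialize()
            if isinstance(s, OrExpr) or (isinstance(s, AndExpr) and not s.complex):
                # top-level spaces separate steps, so inner structure needs parens
                if " " in text or isinstance(s, OrExpr):
                    text = f"({text})" if isinstance(s, AndExpr) else text
            out.append(text)
        return " ".join(out)


def _tokenize(text: str):
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            tokens.append((" ", i))
            while i < len(text) and text[i].isspace():
                i += 1
            continue
        if ch in "(),+-":
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < len(text) and (text[j].isalnum() or text[j] in "_.:"):
            j += 1
        if j == i:
            raise ModuleParseError(f"unexpected character {ch!r}", i)
        tokens.append(("ID:" + text[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser; precedence OR(,) < AND(space) < complex(+)."""

    def __init__(self, tokens, length):
        self.tokens = tokens
        self.pos = 0
        self.length = length

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, self.length)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek()[0] == ",":
            self.next()
            terms.append(self.parse_and())
        terms = [t for t in terms if t is not None]
        if not terms:
            return None  # every alternative was optional
        return terms[0] if len(terms) == 1 else OrExpr(tuple(terms))

    def parse_and(self):
        terms = [self.parse_complex()]
        while self.peek()[0] == " ":
            self.next()
            if self.peek()[0] in (")", ",", None):
                break
            terms.append(self.parse_complex())
        terms = [t for t in terms if t is not None]
        if not terms:
            return None  # all components optional: group contributes nothing
        return terms[0] if len(terms) == 1 else AndExpr(tuple(terms), complex=False)

    def parse_complex(self):
        terms = [self.parse_atom(optional=False)]
        while self.peek()[0] in ("+", "-"):
            op, _ = self.next()
            atom = self.parse_atom(optional=(op == "-"))
            if atom is not None:
                terms.append(atom)
        terms = [t for t in terms if t is not None]
        if not terms:
            return None
        return terms[0] if len(terms) == 1 else AndExpr(tuple(terms), complex=True)

    def parse_atom(self, optional: bool):
        tok, pos = self.peek()
        if tok == "-":
            # leading '-': the whole next atom is optional
            self.next()
            self.parse_atom(optional=True)
            return None
        if tok == "(":
            self.next()
            inner = self.parse_or()
            close, cpos = self.next()
            if close != ")":
                raise ModuleParseError("unbalanced parentheses", cpos)
            return None if optional else inner
        if tok is not None and tok.startswith("ID:"):
            self.next()
            return None if optional else KOLeaf(tok[3:])
        raise ModuleParseError("expected KO id or '('", pos)


def parse_module_definition(text: str, module_id: str = "") -> ModuleDefinition:
    """Parse a KEGG-style definition string into an evaluable step structure."""
    if not text or not text.strip():
        raise ModuleParseError("empty definition", 0)
    # split into top-level steps at depth-0 whitespace
    steps, depth, start = [], 0, 0
    spans = []
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced parentheses", i)
        elif ch.isspace() and depth == 0:
            if start < i:
                spans.append((start, i))
            start = i + 1
    if depth != 0:
        raise ModuleParseError("unbalanced parentheses", len(text))
    if start < len(text):
        spans.append((start, len(text)))
    if not spans:
        raise ModuleParseError("empty definition", 0)
    for a, b in spans:
        chunk = text[a:b]
        parser = _Parser(
            [(t, p + a) for t, p in _tokenize(chunk)], b
        )
        expr = parser.parse_or()
        if parser.peek()[0] is not None:
            raise ModuleParseError("trailing tokens", parser.peek()[1])
        if expr is not None:  # fully optional steps ("-Kxxxxx") are dropped
            steps.append(expr)
    if not steps:
        raise ModuleParseError("definition has no mandatory steps", 0)
    return ModuleDefinition(module_id=module_id, steps=tuple(steps))


def module_completeness(definition: ModuleDefinition, ko_set) -> tuple:
    """(fraction of satisfied steps, complete?) for a genome's KO set."""
    ko_set = set(ko_set)
    satisfied = sum(1 for s in definition.steps if s.evaluate(ko_set))
    frac = satisfied / len(definition.steps)
    return frac, frac == 1.0


def fisher_exact_two_sided(table_2x2) -> float:
    """Two-sided Fisher exact p: sum of probabilities of all tables with the
    observed margins whose point probability is <= the observed one."""
    return float(stats.fisher_exact(np.asarray(table_2x2))[1])


def occurrence_contrast(presence: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-function Fisher contrast of occurrence between enriched species sets.

    ``presence`` is species x function boolean; ``labels`` assigns each
    species ``case_enriched`` or ``control_enriched``.  Functions present in
    every species (or absent from all) carry no information and get p = 1.
    """
    labels = labels.reindex(presence.index)
    if labels.isna().any():
        raise ValidationError("every species must be labeled")
    valid = {CASE_ENRICHED, CONTROL_ENRICHED}
    if not set(labels.unique()) <= valid:
        raise ValidationError(f"labels must be within {valid}")
    case_mask = (labels == CASE_ENRICHED).values
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise ValidationError("need >= 1 species per label")
    rows = []
    for fn in presence.columns:
        pres = presence[fn].astype(bool).values
        a = int((pres & case_mask).sum())
        b = int((~pres & case_mask).sum())
        c = int((pres & ~case_mask).sum())
        d = int((~pres & ~case_mask).sum())
        if pres.all() or not pres.any():
            p = 1.0
        else:
            p = fisher_exact_two_sided([[a, b], [c, d]])
        f_case = a / case_mask.sum()
        f_ctrl = c / (~case_mask).sum()
        if f_case > f_ctrl:
            direction = CASE_ENRICHED
        elif f_case < f_ctrl:
            direction = CONTROL_ENRICHED
        else:
            direction = NONE
        rows.append(
            {
                "function": fn,
                "n_case_present": a,
                "n_control_present": c,
                "freq_case": f_case,
                "freq_control": f_ctrl,
                "p": p,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).set_index("function")
    out["q"] = q_values(out["p"].values)
    return out


def completeness_contrast(
    definitions: dict, ko_sets: dict, labels: pd.Series, min_completeness: float = 1.0
) -> pd.DataFrame:
    """Fisher contrast on the complete/incomplete dichotomy per module.

    ``definitions`` maps module id -> ModuleDefinition; ``ko_sets`` maps
    species id -> set of KOs.  A species counts as carrying the module when
    its completeness fraction is >= ``min_completeness`` (default: fully
    complete).
    """
    species = list(labels.index)
    data = {}
    for mid, definition in definitions.items():
        col = []
        for sp in species:
            frac, _ = module_completeness(definition, ko_sets.get(sp, ()))
            col.append(frac >= min_completeness)
        data[mid] = col
    presence = pd.DataFrame(data, index=species)
    return occurrence_contrast(presence, labels)


def default_capability_rules() -> pd.DataFrame:
    """The shipped marker-enzyme rule table (editable TSV, versioned)."""
    with resources.files("metasig.data").joinpath("capability_rules.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def capability_profile(annotations, rule_table: pd.DataFrame | None = None) -> dict:
    """Biosynthesis-capability flags from a species' annotation identifiers.

    A capability is true iff at least one of its marker identifiers (KO ids
    or enzyme names, case-insensitive) occurs in ``annotations``.
    """
    if rule_table is None:
        rule_table = default_capability_rules()
    required = {"capability", "markers"}
    if not required <= set(rule_table.columns):
        raise ValidationError(f"rule table needs columns {sorted(required)}")
    ann = {str(a).strip().lower() for a in annotations}
    profile = {}
    for _, row in rule_table.iterrows():
        markers = [m.strip().lower() for m in str(row["markers"]).split(",") if m.strip()]
        if not markers:
            raise ValidationError(f"capability {row['capability']!r} has no markers")
        profile[row["capability"]] = any(m in ann for m in markers)
    return profile


def functional_abundance(
    gene_abundance: pd.DataFrame, gene_map: pd.DataFrame
) -> pd.DataFrame:
    """Function abundance = per-sample sum of member-gene abundances.

    ``gene_abundance`` is samples x genes; ``gene_map`` has columns
    ``gene_id`` and ``function_id``.  Genes absent from the map are ignored;
    duplicate gene ids in the map are an error.
    """
    if gene_map.empty:
        return pd.DataFrame(index=gene_abundance.index)
    if gene_map["gene_id"].duplicated().any():
        dups = gene_map.loc[gene_map["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene ids in map: {dups}")
    mapped = gene_map[gene_map["gene_id"].isin(gene_abundance.columns)]
    if mapped.empty:
        return pd.DataFrame(index=gene_abundance.index)
    sub = gene_abundance[mapped["gene_id"]]
    sub.columns = pd.Index(mapped["function_id"].values, name="function")
    return sub.T.groupby(level=0).sum().T
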