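"""Mapping token-level attribution scores onto molecular graphs.

Transformer explanations for SMILES classifiers arrive as signed scores on
string tokens.  Chemistry happens on atoms, so this module aligns tokens to
character spans, maps characters to atoms (skipping purely syntactic symbols
such as ring-closure digits, parentheses and bond characters), divides each
token's score equally among the distinct atoms it touches, and classifies the
aggregated per-atom scores as positive / negative / neutral for rendering.

The per-atom sum is conservative: the total atom score equals the total score
of all atom-touching tokens.  Scores on purely syntactic tokens are known
string-representation artefacts and are dropped (optionally smeared onto
neighboring atoms via ``syntax_to_neighbors``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import networkx as nx
from rdkit import Chem

__all__ = [
    "TokenAttribution",
    "AtomAttribution",
    "AtomClass",
    "tokenize_smiles",
    "align_tokens",
    "char_to_atom",
    "atom_attributions",
    "classify_atoms",
    "render_annotation",
]

DEFAULT_NEUTRAL_BAND = 0.15

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]|Cl|Br|%\d{2}|\d|[cnopsb]|[BCNOPSFI*]|[=#:/\\().+\-~$@]"
)

_TWO_LETTER = ("Cl", "Br")
_ATOM_CHARS = set("BCNOPSFI*") | set("bcnops")


class AtomClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class TokenAttribution:
    """A token string, its half-open character span, and its signed score."""

    token: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class AtomAttribution:
    atom_index: int
    score: float
    cls: AtomClass


def tokenize_smiles(smiles: str) -> list[str]:
    """Lexical tokenization of a SMILES string (one token per symbol).

    Bracket atoms, two-letter halogens and ``%nn`` ring closures are kept
    whole; tokens concatenate exactly to the input.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"cannot tokenize SMILES {smiles!r}")
    return tokens


def align_tokens(smiles: str, tokens: list[str]) -> list[tuple[int, int]]:
    """Greedy left-to-right alignment of tokens to character spans.

    Spans partition ``[0, len(smiles))``; a mismatch raises an error naming
    the first divergent position.
    """
    spans: list[tuple[int, int]] = []
    pos = 0
    for tok in tokens:
        end = pos + len(tok)
        if smiles[pos:end] != tok:
            div = pos
            for k, ch in enumerate(tok):
                if pos + k >= len(smiles) or smiles[pos + k] != ch:
                    div = pos + k
                    break
            raise ValueError(
                f"token {tok!r} diverges from SMILES at position {div}"
            )
        spans.append((pos, end))
        pos = end
    if pos != len(smiles):
        raise ValueError(
            f"tokens cover only [0, {pos}) of a SMILES of length {len(smiles)}"
        )
    return spans


def char_to_atom(smiles: str) -> list[int | None]:
    """Map each character of a SMILES string to its atom index, or None.

    Atoms are numbered in traversal (writing) order, which matches RDKit's
    atom numbering when the molecule is built from this string.  All
    characters of a bracket atom ``[...]`` (including stereo markers and
    bracket hydrogens) map to that atom; both letters of Cl/Br map to one
    atom; ring-closure digits, ``%nn`` closures, parentheses, bond symbols
    and dots map to None.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    mapping: list[int | None] = [None] * len(smiles)
    i = 0
    atom = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.index("]", i)
            for k in range(i, j + 1):
                mapping[k] = atom
            atom += 1
            i = j + 1
        elif smiles[i : i + 2] in _TWO_LETTER:
            mapping[i] = atom
            mapping[i + 1] = atom
            atom += 1
            i += 2
        elif ch in _ATOM_CHARS:
            mapping[i] = atom
            atom += 1
            i += 1
        elif ch == "%":
            i += 3  # %nn ring closure
        else:
            i += 1  # digit, bond, parenthesis, '.', '@' outside brackets
    if atom != mol.GetNumAtoms():
        raise ValueError(
            f"scanned {atom} atoms but RDKit sees {mol.GetNumAtoms()} in {smiles!r}"
        )
    return mapping


def atom_attributions(
    smiles: str,
    attrs: list[TokenAttribution],
    neutral_band: float = DEFAULT_NEUTRAL_BAND,
    syntax_to_neighbors: bool = False,
) -> list[AtomAttribution]:
    """Aggregate token scores onto atoms (equal share per touched atom).

    Each token's score is divided equally among the distinct atoms its span
    touches; tokens touching no atom contribute nothing unless
    ``syntax_to_neighbors`` is set, in which case their score is shared by the
    atoms adjacent (in string order) to the syntactic span.
    """
    mapping = char_to_atom(smiles)
    align_tokens(smiles, [a.token for a in attrs])  # validates the partition
    n_atoms = max((m for m in mapping if m is not None), default=-1) + 1
    scores = [0.0] * n_atoms
    for a in attrs:
        touched = sorted({mapping[i] for i in range(a.start, a.end) if mapping[i] is not None})
        if not touched and syntax_to_neighbors:
            left = next((mapping[i] for i in range(a.start - 1, -1, -1) if mapping[i] is not None), None)
            right = next((mapping[i] for i in range(a.end, len(smiles)) if mapping[i] is not None), None)
            touched = sorted({m for m in (left, right) if m is not None})
        if not touched:
            continue
        share = a.score / len(touched)
        for m in touched:
            scores[m] += share
    classes = classify_atoms(scores, neutral_band)
    return [AtomAttribution(i, scores[i], classes[i]) for i in range(n_atoms)]


def classify_atoms(scores: list[float], neutral_band: float = DEFAULT_NEUTRAL_BAND) -> list[AtomClass]:
    """Classify signed atom scores relative to the maximum magnitude.

    ``|score| <= neutral_band * max|score|`` -> neutral, else the sign
    decides.  All-zero input is all neutral.
    """
    if neutral_band < 0:
        raise ValueError("neutral_band must be non-negative")
    peak = max((abs(s) for s in scores), default=0.0)
    out = []
    for s in scores:
        if peak == 0.0 or abs(s) <= neutral_band * peak:
            out.append(AtomClass.NEUTRAL)
        elif s > 0:
            out.append(AtomClass.POSITIVE)
        else:
            out.append(AtomClass.NEGATIVE)
    return out

_CLASS_COLORS = {
    AtomClass.POSITIVE: "blue",
    AtomClass.NEGATIVE: "red",
    AtomClass.NEUTRAL: "yellow",
}

_RGB = {
    AtomClass.POSITIVE: (0.55, 0.75, 1.0),
    AtomClass.NEGATIVE: (1.0, 0.55, 0.55),
    AtomClass.NEUTRAL: (1.0, 1.0, 0.6),
}


def render_annotation(
    smiles: str,
    atoms: list[AtomAttribution],
    out: str | Path,
    format: str = "svg",
) -> Path:
    """Export an annotated molecule: SVG depiction or GraphML graph.

    SVG colors atoms by class (positive blue, negative red, neutral yellow);
    GraphML stores score, class and color per node and the bond graph as
    edges.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    if len(atoms) != mol.GetNumAtoms():
        raise ValueError(
            f"{len(atoms)} attributions for a molecule with {mol.GetNumAtoms()} atoms"
        )
    out = Path(out)
    if format == "svg":
        from rdkit.Chem.Draw import rdMolDraw2D

        drawer = rdMolDraw2D.MolDraw2DSVG(450, 450)
        highlight = [a.atom_index for a in atoms]
        colors = {a.atom_index: _RGB[a.cls] for a in atoms}
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol, highlightAtoms=highlight, highlightAtomColors=colors
        )
        drawer.FinishDrawing()
        out.write_text(drawer.GetDrawingText())
    elif format == "graphml":
        g = nx.Graph()
        by_index = {a.atom_index: a for a in atoms}
        for rd_atom in mol.GetAtoms():
            a = by_index[rd_atom.GetIdx()]
            g.add_node(
                rd_atom.GetIdx(),
                symbol=rd_atom.GetSymbol(),
                score=float(a.score),
                cls=a.cls.value,
                color=_CLASS_COLORS[a.cls],
            )
        for bond in mol.GetBonds():
            g.add_edge(
                bond.GetBeginAtomIdx(),
                bond.GetEndAtomIdx(),
                order=bond.GetBondTypeAsDouble(),
            )
        nx.write_graphml(g, out)
    else:
        raise ValueError(f"unknown format {format!r}")
    return out
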