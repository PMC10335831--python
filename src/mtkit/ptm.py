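"""Tabulation of alpha-tubulin C-terminal tail glutamylation from PSM tables.

Glutamylation adds glutamate residues as a branched sidechain (mass
+129.04259 Da per added Glu, the glutamyl residue monoisotopic mass) to
glutamates of the tubulin C-terminal tail.  In *Drosophila* ovaries the
modifiable sites of the general isotypes alphaTub84B and alphaTub84D —
whose C-terminal peptides are sequence-identical, hence pooled as
"alphaTub84B/D" — are E443, E445, E448 and E449, in the tail
G442-E-G-E-G-A-E-E-Y450.  The maternal isotype alphaTub67C ends in Phe
rather than Tyr and is tabulated separately.

A +57.021464 Da delta is mass-identical to glycylation *and* to the
alkylation artifact of sample preparation; such mods are flagged ambiguous
and never counted as glutamylation.

Counts are the canonical quantity; percentages are always recomputed from
counts and rounded half-up to whole percent, the style of printed
PSM-frequency tables.
"""

from __future__ import annotations

import re
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .errors import ConfigurationError, UndefinedResultError

__all__ = [
    "GLU_RESIDUE_MASS",
    "GLY_AMBIGUOUS_MASS",
    "IsotypeTail",
    "TailModel",
    "DEFAULT_TAIL_MODEL",
    "PSMRecord",
    "GluSummary",
    "assign_isotype",
    "parse_mods",
    "sidechain_length",
    "SidechainResult",
    "summarize",
    "isotype_ratio",
    "enumerate_isoforms",
]

GLU_RESIDUE_MASS = 129.04259  # Da, monoisotopic glutamyl residue
GLY_AMBIGUOUS_MASS = 57.021464  # Da, glycylation == Cys-alkylation artifact

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_MOD_RE = re.compile(r"^\s*([A-Z])(\d+)\(\+?(-?\d+(?:\.\d+)?)\)\s*$")


@dataclass(frozen=True)
class IsotypeTail:
    """C-terminal tail of one isotype: sequence, residue numbering and
    modifiable (glutamylatable) sites."""

    name: str
    tail: str  # C-terminal suffix that a complete peptide must end with
    start_residue: int  # residue number of tail[0]
    sites: tuple[int, ...] = ()  # residue numbers of modifiable glutamates

    def __post_init__(self) -> None:
        if not self.tail or any(c not in _AA for c in self.tail):
            raise ConfigurationError(f"invalid tail sequence {self.tail!r}")
        for s in self.sites:
            off = s - self.start_residue
            if not (0 <= off < len(self.tail)) or self.tail[off] != "E":
                raise ConfigurationError(
                    f"{self.name}: site E{s} does not match tail {self.tail!r}"
                )

    def site_labels(self) -> tuple[str, ...]:
        return tuple(f"E{s}" for s in self.sites)


@dataclass(frozen=True)
class TailModel:
    """The set of isotype tails used for suffix-based isotype assignment."""

    tails: tuple[IsotypeTail, ...]

    def by_name(self, name: str) -> IsotypeTail:
        for t in self.tails:
            if t.name == name:
                return t
        raise KeyError(name)


# alphaTub84B/D: genuine tail per the residue numbering E443/E445/E448/E449
# (G442...Y450).  alphaTub67C: Phe-terminal tail; the exact sequence is a
# synthetic placeholder (configurable) — only its distinctness and terminal
# F matter for assignment.
TAIL_84BD = IsotypeTail(
    name="alphaTub84B/D", tail="GEGEGAEEY", start_residue=442, sites=(443, 445, 448, 449)
)
TAIL_67C = IsotypeTail(name="alphaTub67C", tail="GEEEGEEF", start_residue=440, sites=())
DEFAULT_TAIL_MODEL = TailModel(tails=(TAIL_84BD, TAIL_67C))


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with parsed modifications."""

    psm_id: str
    genotype: str
    peptide: str
    mods: tuple[tuple[str, float], ...]  # (site label, delta mass Da)
    isotype: str


def assign_isotype(peptide: str, tail_model: TailModel = DEFAULT_TAIL_MODEL) -> str:
    """Assign an isotype by C-terminal suffix match against the tail model.

    A peptide must carry the complete tail primary sequence to be assigned;
    anything else (including ragged C-termini) is ``"other"``.
    """
    if not peptide:
        raise ConfigurationError("empty peptide")
    pep = peptide.strip().upper()
    bad = set(pep) - _AA
    if bad:
        raise ConfigurationError(f"non-amino-acid characters in peptide: {sorted(bad)}")
    best = None
    for t in tail_model.tails:
        if pep.endswith(t.tail):
            if best is None or len(t.tail) > len(best.tail):
                best = t
    return best.name if best is not None else "other"


def parse_mods(mods_str: str | float | None) -> tuple[tuple[str, float], ...]:
    """Parse a semicolon-separated modification string 'E448(+129.0426);...'
    into (site, delta) pairs."""
    if mods_str is None or (isinstance(mods_str, float) and np.isnan(mods_str)):
        return ()
    s = str(mods_str).strip()
    if not s:
        return ()
    out = []
    for token in s.split(";"):
        m = _MOD_RE.match(token)
        if m is None:
            raise ConfigurationError(f"cannot parse modification token {token!r}")
        res, pos, delta = m.group(1), int(m.group(2)), float(m.group(3))
        out.append((f"{res}{pos}", delta))
    return tuple(out)


@dataclass(frozen=True)
class SidechainResult:
    total: int  # total added Glu across sites
    per_site: dict = field(default_factory=dict)  # site label -> n added Glu
    ambiguous: bool = False  # a +57.021464 delta was seen (never counted)
    unknown: tuple[str, ...] = ()  # mods matching neither mass series


def sidechain_length(
    mods: Sequence[tuple[str, float]] | str | None,
    tolerance_da: float = 0.01,
) -> SidechainResult:
    """Decompose modification mass deltas into added-Glu counts per site.

    Each delta is matched to ``n x 129.04259`` Da within ``tolerance_da``
    per Glu.  Deltas matching +57.021464 Da are flagged ambiguous
    (glycylation vs alkylation artifact) and contribute zero.  Deltas
    matching neither series raise an unknown-mod warning and are skipped.
    """
    if not isinstance(mods, (list, tuple)):
        mods = parse_mods(mods)  # str / None / NaN cell from a TSV

    per_site: dict[str, int] = {}
    ambiguous = False
    unknown: list[str] = []
    for site, delta in mods:
        if abs(delta - GLY_AMBIGUOUS_MASS) <= tolerance_da:
            ambiguous = True
            continue
        n = int(round(delta / GLU_RESIDUE_MASS))
        if n >= 1 and abs(delta - n * GLU_RESIDUE_MASS) <= tolerance_da * n:
            per_site[site] = per_site.get(site, 0) + n
        else:
            unknown.append(f"{site}(+{delta})")
    if unknown:
        warnings.warn(f"unresolvable modification masses: {unknown}", stacklevel=2)
    return SidechainResult(
        total=sum(per_site.values()),
        per_site=per_site,
        ambiguous=ambiguous,
        unknown=tuple(unknown),
    )


@dataclass(frozen=True)
class GluSummary:
    """Per genotype x isotype glutamylation tabulation.

    ``counts``: DataFrame with columns genotype, isotype, total_psm, n_0e,
    n_1e, n_2e, n_3e, n_over3e.  ``table()`` derives the percentage view.
    """

    counts: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Percentage table (rounded half-up): % 1E, 2E, 3E and total modified."""
        rows = []
        for _, r in self.counts.iterrows():
            total = int(r["total_psm"])
            n_mod = int(r["n_1e"] + r["n_2e"] + r["n_3e"] + r["n_over3e"])
            rows.append(
                {
                    "genotype": r["genotype"],
                    "isotype": r["isotype"],
                    "total_psm": total,
                    "pct_1e": percent(int(r["n_1e"]), total),
                    "pct_2e": percent(int(r["n_2e"]), total),
                    "pct_3e": percent(int(r["n_3e"]), total),
                    "pct_modified": percent(n_mod, total),
                }
            )
        return pd.DataFrame(rows)

    def cell(self, genotype: str, isotype: str) -> pd.Series:
        sel = (self.counts["genotype"] == genotype) & (self.counts["isotype"] == isotype)
        if not sel.any():
            raise KeyError((genotype, isotype))
        return self.counts[sel].iloc[0]


def summarize(
    psm_table: pd.DataFrame,
    tail_model: TailModel = DEFAULT_TAIL_MODEL,
    tolerance_da: float = 0.01,
) -> GluSummary:
    """Tabulate sidechain-length counts per genotype and isotype.

    The input needs columns ``genotype``, ``peptide`` and ``mods``
    (semicolon-separated ``SITE(+MASS)``).  Peptides that do not carry a
    complete isotype tail ("other") are excluded from the totals, which is
    what restricting the tabulation to C-terminal peptides containing the
    entire primary sequence means operationally.
    """
    required = {"genotype", "peptide", "mods"}
    missing = required - set(psm_table.columns)
    if missing:
        raise ConfigurationError(f"PSM table lacks columns: {sorted(missing)}")
    recs = []
    for _, row in psm_table.iterrows():
        isotype = assign_isotype(str(row["peptide"]), tail_model)
        if isotype == "other":
            continue
        res = sidechain_length(row["mods"], tolerance_da=tolerance_da)
        recs.append((str(row["genotype"]), isotype, res.total))
    if not recs:
        warnings.warn("no PSM matched any isotype tail", stacklevel=2)
        return GluSummary(
            counts=pd.DataFrame(
                columns=[
                    "genotype", "isotype", "total_psm",
                    "n_0e", "n_1e", "n_2e", "n_3e", "n_over3e",
                ]
            )
        )
    df = pd.DataFrame(recs, columns=["genotype", "isotype", "length"])
    rows = []
    for (genotype, isotype), grp in df.groupby(["genotype", "isotype"], sort=False):
        lengths = grp["length"].to_numpy()
        rows.append(
            {
                "genotype": genotype,
                "isotype": isotype,
                "total_psm": len(lengths),
                "n_0e": int(np.sum(lengths == 0)),
                "n_1e": int(np.sum(lengths == 1)),
                "n_2e": int(np.sum(lengths == 2)),
                "n_3e": int(np.sum(lengths == 3)),
                "n_over3e": int(np.sum(lengths > 3)),
            }
        )
    return GluSummary(counts=pd.DataFrame(rows))


def isotype_ratio(
    summary: GluSummary,
    genotype: str,
    numerator: str = "alphaTub84B/D",
    denominator: str = "alphaTub67C",
) -> float:
    """Ratio of total PSM counts between two isotypes, 1-decimal rounded."""
    try:
        num = int(summary.cell(genotype, numerator)["total_psm"])
        den = int(summary.cell(genotype, denominator)["total_psm"])
    except KeyError as e:
        raise UndefinedResultError(f"missing isotype cell {e.args[0]!r}") from e
    if den == 0:
        raise UndefinedResultError("denominator isotype has zero PSMs")
    return round_half_up(num / den, 1)


def enumerate_isoforms(n_sites: int, total_e: int) -> list[tuple[int, ...]]:
    """All distributions of ``total_e`` added glutamates over ``n_sites``
    sites (weak compositions); the count is C(total_e + n_sites - 1, n_sites - 1)."""
    if n_sites < 1 or total_e < 0:
        raise ConfigurationError("need n_sites >= 1 and total_e >= 0")
    out = []
    for combo in combinations_with_replacement(range(n_sites), total_e):
        counts = [0] * n_sites
        for c in combo:
            counts[c] += 1
        out.append(tuple(counts))
    assert len(out) == comb(total_e + n_sites - 1, n_sites - 1)
    return out
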