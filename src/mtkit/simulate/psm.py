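"""Synthetic PSM tables with programmed per-genotype sidechain-length
distributions over the alphaTub84B/D tail sites E443/E445/E448/E449.

Two sampling modes: multinomial draws of the length categories, or an
*exact-counts* mode in which the category counts are assigned
deterministically (largest-remainder apportionment of ``probs * n``),
which reproduces a published count table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..ptm import GLU_RESIDUE_MASS, TAIL_67C, TAIL_84BD

__all__ = ["PSMSimConfig", "simulate_psm_table"]

# full C-terminal peptides used for simulated PSMs: a short upstream
# context plus the complete tail primary sequence
_PEPTIDE_84BD = "SVEGEGEGAEEY"
assert _PEPTIDE_84BD.endswith(TAIL_84BD.tail)
_PEPTIDE_67C = "SA" + TAIL_67C.tail

_PROB_TOL = 1e-9


def _check_probs(name: str, probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 1 or np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ConfigurationError(f"{name} must be a nonnegative probability vector")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{name} must sum to 1 (got {p.sum():.12g})")
    return p


@dataclass(frozen=True)
class PSMSimConfig:
    """Programmed glutamylation state of one genotype's PSM population.

    ``sidechain_probs``: probability of 0, 1, 2, 3 total added Glu on an
    alphaTub84B/D C-terminal peptide.  ``site_weights``: probabilities of
    placing each added Glu on E443, E445, E448, E449.  alphaTub67C
    peptides default to entirely unmodified.
    """

    n_psm_84bd: int = 58
    n_psm_67c: int = 12
    sidechain_probs: tuple[float, ...] = (17 / 58, 29 / 58, 8 / 58, 4 / 58)
    sidechain_probs_67c: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    site_weights: tuple[float, ...] = (0.15, 0.45, 0.2, 0.2)
    genotype: str = "w"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_psm_84bd < 0 or self.n_psm_67c < 0:
            raise ConfigurationError("PSM counts must be >= 0")
        _check_probs("sidechain_probs", self.sidechain_probs)
        _check_probs("sidechain_probs_67c", self.sidechain_probs_67c)
        w = _check_probs("site_weights", self.site_weights)
        if w.size != len(TAIL_84BD.sites):
            raise ConfigurationError(
                f"site_weights needs {len(TAIL_84BD.sites)} entries, got {w.size}"
            )


def _exact_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n over the categories."""
    raw = probs * n
    base = np.floor(raw).astype(int)
    rem = n - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _mods_string(site_counts: dict[int, int]) -> str:
    parts = [
        f"E{site}(+{n * GLU_RESIDUE_MASS:.4f})"
        for site, n in sorted(site_counts.items())
    ]
    return ";".join(parts)


def simulate_psm_table(cfg: PSMSimConfig, exact_counts: bool = False) -> pd.DataFrame:
    """Generate a PSM table (TSV-writable DataFrame).

    Columns: psm_id, genotype, isotype_hint, peptide, mods, score.
    With ``exact_counts=True`` the number of PSMs in each sidechain-length
    category is assigned (not drawn); site placement of the added
    glutamates still follows ``site_weights`` through the seeded RNG.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = TAIL_84BD.sites
    rows = []

    def emit(isotype_hint: str, peptide: str, probs, n: int) -> None:
        p = np.asarray(probs, dtype=float)
        if n == 0:
            return
        if exact_counts:
            counts = _exact_counts(p, n)
        else:
            counts = rng.multinomial(n, p)
        lengths = np.repeat(np.arange(p.size), counts)
        for ln in lengths:
            site_counts: dict[int, int] = {}
            if ln > 0:
                placed = rng.choice(len(sites), size=int(ln), p=np.asarray(cfg.site_weights))
                for s in placed:
                    site_counts[sites[s]] = site_counts.get(sites[s], 0) + 1
            rows.append(
                {
                    "psm_id": f"psm{len(rows):05d}",
                    "genotype": cfg.genotype,
                    "isotype_hint": isotype_hint,
                    "peptide": peptide,
                    "mods": _mods_string(site_counts),
                    "score": float(np.round(rng.uniform(20, 80), 2)),
                }
            )

    emit("alphaTub84B/D", _PEPTIDE_84BD, cfg.sidechain_probs, cfg.n_psm_84bd)
    emit("alphaTub67C", _PEPTIDE_67C, cfg.sidechain_probs_67c, cfg.n_psm_67c)
    return pd.DataFrame(
        rows, columns=["psm_id", "genotype", "isotype_hint", "peptide", "mods", "score"]
    )
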