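"""Experimental design construction: fractional factorial, central
composite, and multilevel D-optimal designs, with alias-structure algebra.

Designs live in coded units (-1/+1 cube, star distance ``alpha`` for axial
points) and carry the natural-unit settings obtained through each factor's
coded->natural mapping, hard-bound clipping and instrument rounding.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignInfeasibleError, InvalidValueError, SchemaError
from .factors import Factor
from .terms import Term, build_matrix

__all__ = [
    "DesignRow",
    "DesignMatrix",
    "AliasStructure",
    "generate_ffd",
    "generate_ccd",
    "generate_d_optimal",
    "design_to_csv",
    "design_from_csv",
]


# ---------------------------------------------------------------------------
# Alias algebra for two-level fractional factorials
# ---------------------------------------------------------------------------

# Standard minimum-aberration generators for 2^(k-p) designs we support.
# Words are given over factor letters A, B, C, ... in factor order.
_GENERATOR_TABLE: dict[tuple[int, int], tuple[str, ...]] = {
    (4, 1): ("D=ABC",),
    (5, 1): ("E=ABCD",),
    (5, 2): ("D=AB", "E=AC"),
    (6, 2): ("E=ABC", "F=BCD"),
    (7, 3): ("E=ABC", "F=BCD", "G=ACD"),
    (8, 4): ("E=BCD", "F=ACD", "G=ABC", "H=ABD"),
}


def _word_xor(a: frozenset, b: frozenset) -> frozenset:
    return frozenset(a ^ b)


@dataclass(frozen=True)
class AliasStructure:
    """Defining relation of a regular two-level fractional factorial.

    ``defining_words`` are the 2^p - 1 non-identity words of the defining
    relation, each a frozenset of factor letters.  The resolution is the
    length of the shortest word; a full factorial has no words and its
    resolution is reported as the string ``"full"``.
    """

    letters: tuple  # factor letters in factor order, e.g. ("A", ..., "G")
    factor_names: tuple  # parallel tuple of real factor names
    defining_words: frozenset  # of frozensets of letters

    @property
    def resolution(self):
        if not self.defining_words:
            return "full"
        return min(len(w) for w in self.defining_words)

    def _to_letters(self, factors: Iterable[str]) -> frozenset:
        m = {n: l for n, l in zip(self.factor_names, self.letters)}
        out = set()
        for f in factors:
            if f in m:
                out.add(m[f])
            elif f in self.letters:
                out.add(f)
            else:
                raise SchemaError(f"unknown factor {f!r}")
        return frozenset(out)

    def _to_names(self, letters: frozenset) -> tuple:
        m = {l: n for n, l in zip(self.factor_names, self.letters)}
        return tuple(sorted((m[l] for l in letters), key=self.factor_names.index))

    def aliases_of(self, factors: Iterable[str], max_order: Optional[int] = 2):
        """Effects confounded with the effect on ``factors``.

        Returns a set of factor-name tuples.  By default only aliases up to
        two-factor interactions are reported (the orders one reads off a
        screening-design alias table); pass ``max_order=None`` for all.
        """
        word0 = self._to_letters(factors)
        out = set()
        for w in self.defining_words:
            alias = _word_xor(word0, w)
            if not alias:
                continue
            if max_order is not None and len(alias) > max_order:
                continue
            out.add(self._to_names(alias))
        return out

    def alias_map(self, max_order: int = 2) -> dict:
        """Alias sets for every main effect and two-factor interaction."""
        out = {}
        names = self.factor_names
        effects = [(n,) for n in names] + [
            (a, b) for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        for eff in effects:
            out[eff] = self.aliases_of(eff, max_order=max_order)
        return out


def expand_defining_relation(generator_words: Sequence[frozenset]) -> frozenset:
    """All 2^p - 1 products of the p generator words (mod-2 set algebra)."""
    words = set()
    p = len(generator_words)
    for r in range(1, p + 1):
        for combo in itertools.combinations(generator_words, r):
            w = frozenset()
            for g in combo:
                w = _word_xor(w, g)
            if w:
                words.add(w)
    return frozenset(words)


# ---------------------------------------------------------------------------
# Design containers
# ---------------------------------------------------------------------------


@dataclass
class DesignRow:
    run_id: int
    point_type: str  # factorial | axial | center
    coded: np.ndarray
    natural: np.ndarray
    n_replicates: int = 1
    clipped: tuple = ()  # names of factors whose setting hit a hard bound


@dataclass
class DesignMatrix:
    factors: list
    rows: list
    design_kind: str  # ffd | ccd | d_optimal | ofat
    alpha: Optional[float] = None
    generators: tuple = ()
    alias: Optional[AliasStructure] = None
    log_det: Optional[float] = None  # d_optimal objective at the optimum

    @property
    def factor_names(self) -> list:
        return [f.name for f in self.factors]

    def coded_array(self) -> np.ndarray:
        return np.array([r.coded for r in self.rows], dtype=float)

    def natural_array(self) -> np.ndarray:
        return np.array([r.natural for r in self.rows], dtype=float)

    def n_runs(self) -> int:
        return len(self.rows)

    def to_frame(self, expand_replicates: bool = False) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            reps = range(1, row.n_replicates + 1) if expand_replicates else [None]
            for rep in reps:
                rec = {"run_id": row.run_id, "point_type": row.point_type}
                if rep is not None:
                    rec["replicate"] = rep
                else:
                    rec["n_replicates"] = row.n_replicates
                for f, nat, cod in zip(self.factors, row.natural, row.coded):
                    rec[f.name] = nat
                    rec[f"{f.name}_coded"] = cod
                if row.clipped:
                    rec["clipped"] = "+".join(row.clipped)
                recs.append(rec)
        return pd.DataFrame(recs)

    def randomized_run_order(self, seed: int) -> list:
        """Run ids in a seeded random measurement order (replicates of a run
        are executed back-to-back, so only run order is shuffled)."""
        rng = np.random.default_rng(seed)
        ids = [r.run_id for r in self.rows]
        return list(rng.permutation(ids))


def _rows_from_coded(
    factors: Sequence[Factor],
    coded: np.ndarray,
    point_types: Sequence[str],
    n_replicates: int,
) -> list:
    rows = []
    for i, (pt, cvec) in enumerate(zip(point_types, coded), start=1):
        natural = np.array([f.decode(c) for f, c in zip(factors, cvec)])
        clipped = tuple(f.name for f, c in zip(factors, cvec) if f.would_clip(c))
        rows.append(
            DesignRow(
                run_id=i,
                point_type=pt,
                coded=np.asarray(cvec, dtype=float),
                natural=natural,
                n_replicates=n_replicates,
                clipped=clipped,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_ffd(
    factors: Sequence[Factor],
    p: int = 3,
    n_center: int = 3,
    n_replicates: int = 2,
    resolution_target: Optional[int] = None,
) -> tuple:
    """Regular two-level fractional factorial 2^(k-p) with center points.

    Uses the standard minimum-aberration generator table; for the
    seven-factor screening case (k=7, p=3) the generators are E=ABC,
    F=BCD, G=ACD, giving a resolution IV design in 16 factorial runs.

    Returns ``(DesignMatrix, AliasStructure)``.
    """
    k = len(factors)
    if p < 0 or p >= k:
        raise DesignInfeasibleError(f"invalid fraction p={p} for k={k}")
    letters = tuple(string.ascii_uppercase[:k])
    names = tuple(f.name for f in factors)

    n_base = k - p
    base = np.array(list(itertools.product([-1.0, 1.0], repeat=n_base)))
    # standard (Yates-like) order: first base factor varies slowest
    if p == 0:
        coded_fact = base
        gen_words: list[frozenset] = []
        gen_strs: tuple = ()
    else:
        key = (k, p)
        if key not in _GENERATOR_TABLE:
            raise DesignInfeasibleError(
                f"no generator table entry for 2^({k}-{p}) design"
            )
        gen_strs = _GENERATOR_TABLE[key]
        cols = {letters[i]: base[:, i] for i in range(n_base)}
        gen_words = []
        for gs in gen_strs:
            lhs, rhs = gs.split("=")
            prod = np.ones(base.shape[0])
            for l in rhs:
                prod = prod * cols[l]
            cols[lhs] = prod
            gen_words.append(frozenset(lhs) | frozenset(rhs))
        coded_fact = np.column_stack([cols[l] for l in letters])

    alias = AliasStructure(
        letters=letters,
        factor_names=names,
        defining_words=expand_defining_relation(gen_words),
    )
    if resolution_target is not None and alias.resolution != "full":
        if alias.resolution < resolution_target:
            raise DesignInfeasibleError(
                f"resolution {alias.resolution} < target {resolution_target}"
                f" for 2^({k}-{p})"
            )

    coded = np.vstack([coded_fact, np.zeros((n_center, k))])
    point_types = ["factorial"] * coded_fact.shape[0] + ["center"] * n_center
    rows = _rows_from_coded(factors, coded, point_types, n_replicates)
    design = DesignMatrix(
        factors=list(factors),
        rows=rows,
        design_kind="ffd",
        generators=gen_strs,
        alias=alias,
    )
    return design, alias


def generate_ccd(
    factors: Sequence[Factor],
    alpha: float = 1.35,
    n_center: int = 3,
    n_replicates: int = 2,
) -> DesignMatrix:
    """Central composite design: 2^k cube, 2k axial points at +/- alpha,
    plus center points.

    Axial settings that exceed a factor's hard bound are clipped to the
    bound and the run kept (flagged via ``DesignRow.clipped``), preserving
    the nominal run count.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise InvalidValueError("alpha must be > 0")
    k = len(factors)
    cube = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = []
    for j in range(k):
        for s in (-1.0, 1.0):
            v = np.zeros(k)
            v[j] = s * alpha
            axial.append(v)
    coded = np.vstack([cube, np.array(axial), np.zeros((n_center, k))])
    point_types = ["factorial"] * len(cube) + ["axial"] * len(axial) + [
        "center"
    ] * n_center
    rows = _rows_from_coded(factors, coded, point_types, n_replicates)
    return DesignMatrix(
        factors=list(factors), rows=rows, design_kind="ccd", alpha=alpha
    )


# ---------------------------------------------------------------------------
# D-optimal design by coordinate (Fedorov-style) exchange
# ---------------------------------------------------------------------------


def _logdet_xtx(X: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(X.T @ X)
    return ld if sign > 0 else -np.inf


def generate_d_optimal(
    factors: Sequence[Factor],
    candidates: np.ndarray,
    model_terms: Sequence[Term],
    n_runs: int,
    n_restarts: int = 20,
    seed: int = 0,
    n_replicates: int = 2,
) -> DesignMatrix:
    """Select ``n_runs`` rows from a finite candidate grid maximizing
    det(X'X) for the given model, by greedy exchange with seeded restarts.

    ``candidates`` is an (N, k) array in coded units.  The exchange swaps a
    selected point against an unselected candidate whenever the swap
    increases the determinant, so the objective is non-decreasing; restarts
    guard against local optima.
    """
    candidates = np.asarray(candidates, dtype=float)
    names = [f.name for f in factors]
    Xc = build_matrix(candidates, names, model_terms)
    N, m = Xc.shape
    if n_runs < m:
        raise DesignInfeasibleError(
            f"n_runs={n_runs} < {m} model terms: X'X would be rank deficient"
        )
    if n_runs > N:
        raise DesignInfeasibleError(f"n_runs={n_runs} exceeds {N} candidates")
    if n_runs == N:
        best_idx = np.arange(N)
        best_ld = _logdet_xtx(Xc)
    else:
        rng = np.random.default_rng(seed)
        best_idx, best_ld = None, -np.inf
        for _ in range(max(1, n_restarts)):
            idx = list(rng.choice(N, size=n_runs, replace=False))
            ld = _logdet_xtx(Xc[idx])
            improved = True
            while improved:
                improved = False
                selected = set(idx)
                for pos in range(n_runs):
                    best_swap, best_swap_ld = None, ld
                    for j in range(N):
                        if j in selected:
                            continue
                        trial = idx.copy()
                        trial[pos] = j
                        tld = _logdet_xtx(Xc[trial])
                        if tld > best_swap_ld + 1e-12:
                            best_swap, best_swap_ld = j, tld
                    if best_swap is not None:
                        selected.discard(idx[pos])
                        idx[pos] = best_swap
                        selected.add(best_swap)
                        ld = best_swap_ld
                        improved = True
            if ld > best_ld:
                best_ld, best_idx = ld, np.array(sorted(idx))
    coded = candidates[np.asarray(best_idx)]
    rows = _rows_from_coded(factors, coded, ["factorial"] * len(coded), n_replicates)
    return DesignMatrix(
        factors=list(factors),
        rows=rows,
        design_kind="d_optimal",
        log_det=float(best_ld),
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def design_to_csv(design: DesignMatrix, path) -> None:
    design.to_frame(expand_replicates=True).to_csv(path, index=False)


def design_from_csv(path, factors: Sequence[Factor], design_kind: str = "ffd",
                    alpha: Optional[float] = None) -> DesignMatrix:
    df = pd.read_csv(path)
    required = {"run_id", "point_type"}
    required |= {f.name for f in factors}
    required |= {f"{f.name}_coded" for f in factors}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"design CSV missing columns {sorted(missing)}")
    rows = []
    for run_id, grp in df.groupby("run_id", sort=True):
        first = grp.iloc[0]
        coded = np.array(
            [first[f"{f.name}_coded"] for f in factors], dtype=float
        )
        natural = np.array([first[f.name] for f in factors], dtype=float)
        n_rep = int(grp["replicate"].max()) if "replicate" in grp else int(
            first.get("n_replicates", 1)
        )
        clipped = ()
        if "clipped" in grp and isinstance(first.get("clipped"), str):
            clipped = tuple(first["clipped"].split("+"))
        rows.append(
            DesignRow(
                run_id=int(run_id),
                point_type=str(first["point_type"]),
                coded=coded,
                natural=natural,
                n_replicates=n_rep,
                clipped=clipped,
            )
        )
    return DesignMatrix(
        factors=list(factors), rows=rows, design_kind=design_kind, alpha=alpha
    )
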