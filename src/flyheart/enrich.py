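"""Gene-list intersection and hypergeometric enrichment.

Given a query set of K genes and a reference set of n genes drawn from a
universe of N genes, the enrichment p-value is the upper-tail
hypergeometric probability of observing at least the k genes actually
shared:

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

The tail is computed in log space (log-gamma terms combined with
logsumexp) for numerical safety at genome scale; an exact rational
evaluation is available for small universes.  The observed k is included
in the tail (P(X >= k)), and the test is one-sided -- the enrichment
direction only.

The universe size N is rarely stated alongside published overlap counts.
The default here is 13,500 -- the scale of the Drosophila protein-coding
gene count -- and reports always carry N plus a sensitivity sweep over a
plausible range, because bound-style claims should be robust to N.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "DEFAULT_UNIVERSE_SIZE",
    "normalize_id",
    "read_gene_list",
    "write_gene_list",
    "overlap",
    "hypergeom_pvalue",
    "enrichment_table",
]

#: Default universe size: the scale of the Drosophila protein-coding genome.
DEFAULT_UNIVERSE_SIZE = 13_500

#: Default sensitivity-sweep range for the universe size.
DEFAULT_SWEEP = (10_000, 17_000)

_FBGN_RE = re.compile(r"^fbgn(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene identifiers."""

    name: str
    ids: frozenset

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts and the hypergeometric upper-tail probability."""

    query: str
    reference: str
    k: int              # overlap
    K: int              # query size
    n: int              # reference size
    N: int              # universe size
    p_value: float
    expected: float     # K * n / N
    fold: float         # k / expected


# ---------------------------------------------------------------------------
# Gene-list I/O
# ---------------------------------------------------------------------------

def normalize_id(raw: str) -> str:
    """Trim and case-normalize one identifier.

    FlyBase gene identifiers are canonicalized to ``FBgn`` + digits
    regardless of input case; anything else is uppercased.
    """
    s = str(raw).strip()
    m = _FBGN_RE.match(s)
    if m:
        return f"FBgn{m.group(1)}"
    return s.upper()


def read_gene_list(
    path: str | Path,
    id_col: str | int | None = None,
    name: str | None = None,
) -> GeneSet:
    """Read a gene list from plain text (one ID per line) or TSV.

    With ``id_col`` the file is parsed as TSV with a header and the IDs
    taken from that column (by name or 0-based index).  Identifiers are
    trimmed, case-normalized and de-duplicated; duplicate and empty-line
    counts are reported via logging.
    """
    import logging

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path.name}: empty gene list")

    if id_col is not None:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        col = df.columns[id_col] if isinstance(id_col, int) else id_col
        if col not in df.columns:
            raise ValueError(f"{path.name}: no column {id_col!r} in {list(df.columns)}")
        raw = [str(v) for v in df[col].dropna()]
        n_empty = int(df[col].isna().sum())
    else:
        lines = text.splitlines()
        raw = [ln for ln in (l.strip() for l in lines) if ln]
        n_empty = len(lines) - len(raw)

    ids = [normalize_id(r) for r in raw]
    unique = frozenset(ids)
    if not unique:
        raise ValueError(f"{path.name}: no parsable identifiers")
    n_dup = len(ids) - len(unique)
    if n_dup or n_empty:
        logging.getLogger(__name__).info(
            "%s: %d ids (%d duplicates, %d empty lines dropped)",
            path.name, len(unique), n_dup, n_empty,
        )
    return GeneSet(name or path.stem, unique)


def write_gene_list(geneset: GeneSet, path: str | Path) -> Path:
    """Write one identifier per line, sorted."""
    path = Path(path)
    path.write_text("\n".join(sorted(geneset.ids)) + "\n")
    return path


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def overlap(
    query: GeneSet,
    reference: GeneSet,
    universe: GeneSet | int | None = None,
) -> tuple[int, frozenset]:
    """Exact set intersection, after clipping both sets to the universe.

    Returns ``(k, shared_ids)``.  When ``universe`` is a :class:`GeneSet`,
    query and reference are first restricted to it (clipped counts are
    logged); an integer or ``None`` implies no clipping.
    """
    import logging

    q_ids, r_ids = query.ids, reference.ids
    if isinstance(universe, GeneSet):
        clipped_q = len(q_ids - universe.ids)
        clipped_r = len(r_ids - universe.ids)
        q_ids &= universe.ids
        r_ids &= universe.ids
        if clipped_q or clipped_r:
            logging.getLogger(__name__).info(
                "clipped to universe: %d from %s, %d from %s",
                clipped_q, query.name, clipped_r, reference.name,
            )
    if not q_ids or not r_ids:
        raise ValueError("a set is empty after clipping to the universe")
    shared = frozenset(q_ids & r_ids)
    return len(shared), shared


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------

def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 < K <= N and 0 < n <= N):
        raise ValueError(f"need 0 < K, n <= N; got K={K}, n={n}, N={N}")
    # overlap cannot be smaller than forced by the sizes
    if k < K + n - N:
        raise ValueError(f"k={k} impossible: sets of sizes {K} and {n} in a universe of {N} share at least {K + n - N}")


def hypergeom_pvalue(k: int, K: int, n: int, N: int, exact: bool = False) -> float:
    """Upper-tail probability P(X >= k) of the hypergeometric distribution.

    ``k`` shared genes between a query of size ``K`` and a reference of
    size ``n`` in a universe of ``N``.  Computed in log space; with
    ``exact=True`` the tail is summed with exact rational arithmetic
    (practical for small N).
    """
    _validate_counts(k, K, n, N)
    hi = min(K, n)
    if k <= max(0, K + n - N):
        return 1.0

    if exact:
        total = math.comb(N, n)
        acc = Fraction(0)
        for i in range(k, hi + 1):
            acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
        return float(acc)

    i = np.arange(k, hi + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def enrichment_table(
    pairs,
    universe: GeneSet | int = DEFAULT_UNIVERSE_SIZE,
    sweep: tuple[int, int] | None = DEFAULT_SWEEP,
):
    """One enrichment row per (query, reference) pair.

    ``pairs`` is an iterable of ``(query GeneSet, reference GeneSet)``.
    Returns a DataFrame with columns query, reference, k, K, n, N,
    expected, fold, p plus ``p_min_sweep``/``p_max_sweep`` over the
    universe-size sensitivity range (the endpoints bound p, which is
    monotone in N).
    """
    import pandas as pd

    rows = []
    for query, reference in pairs:
        res = enrich_pair(query, reference, universe, sweep=sweep)
        rows.append(res)
    return pd.DataFrame(rows)


def enrich_pair(
    query: GeneSet,
    reference: GeneSet,
    universe: GeneSet | int = DEFAULT_UNIVERSE_SIZE,
    sweep: tuple[int, int] | None = DEFAULT_SWEEP,
) -> dict:
    """Enrichment statistics for one query/reference pair (dict of one row)."""
    if isinstance(universe, GeneSet):
        N = len(universe)
    else:
        N = int(universe)
    k, _ = overlap(query, reference, universe if isinstance(universe, GeneSet) else None)
    K, n = len(query), len(reference)
    if isinstance(universe, GeneSet):
        K = len(query.ids & universe.ids)
        n = len(reference.ids & universe.ids)
    p = hypergeom_pvalue(k, K, n, N)
    expected = K * n / N
    row = {
        "query": query.name,
        "reference": reference.name,
        "k": k,
        "K": K,
        "n": n,
        "N": N,
        "expected": expected,
        "fold": k / expected if expected > 0 else math.inf,
        "p": p,
    }
    if sweep is not None:
        lo, hi = sweep
        lo = max(lo, max(K, n, K + n - k))  # N must admit the observed counts
        ps = [hypergeom_pvalue(k, K, n, NN) for NN in (lo, hi)]
        row["p_min_sweep"] = min(ps)
        row["p_max_sweep"] = max(ps)
    return row
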