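"""Local term-enrichment analysis of screening hits.

Hits are mapped to unique protein accessions through a user-supplied
PDB-to-accession table, and each annotation term is tested for
over-representation with the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the background universe size, K the term's annotated accessions,
n the hit-list size and k the overlap.  Benjamini-Hochberg correction is
applied within each namespace (BP/MF/CC/pathway) separately, and terms with
q below a threshold (default 0.1) are flagged significant.  An EASE-style
variant (upper tail at k - 1) is available for parity with annotation
servers that use it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentRow",
    "map_ids",
    "hypergeom_p",
    "bh_adjust",
    "enrich",
    "read_annotation_table",
    "read_mapping_table",
]

NAMESPACES = ("BP", "MF", "CC", "pathway")


@dataclass
class AnnotationTable:
    universe: frozenset[str]
    term_members: dict[str, frozenset[str]]
    term_namespace: dict[str, str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe is empty")
        for term, members in self.term_members.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the universe: {sorted(extra)[:5]}"
                )


@dataclass
class EnrichmentRow:
    term: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    significant: bool


def read_annotation_table(path: str | Path,
                          universe: Iterable[str] | None = None) -> AnnotationTable:
    """Read a GAF-like 3-column TSV: accession, term, namespace."""
    members: dict[str, set[str]] = {}
    ns: dict[str, str] = {}
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        acc, term, namespace = line.split("\t")[:3]
        members.setdefault(term, set()).add(acc)
        ns[term] = namespace
        seen.add(acc)
    uni = frozenset(universe) if universe is not None else frozenset(seen)
    return AnnotationTable(
        universe=uni,
        term_members={t: frozenset(m & uni) for t, m in members.items()},
        term_namespace=ns,
    )


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping structure ID -> protein accession."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, acc = line.split("\t")[:2]
        out[sid] = acc
    return out


def map_ids(hits: Iterable, mapping: Mapping[str, str]) -> set[str]:
    """De-duplicated accession set for a hit list; unmapped IDs are logged.

    ``hits`` may contain MatchHit-like objects (with a ``target_id``) or
    plain structure-ID strings.
    """
    accs: set[str] = set()
    for h in hits:
        sid = getattr(h, "target_id", h)
        acc = mapping.get(sid)
        if acc is None:
            logger.warning("no accession mapping for structure %s; excluded", sid)
        else:
            accs.add(acc)
    return accs


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    accessions: Iterable[str],
    annotations: AnnotationTable,
    q_threshold: float = 0.1,
    ease: bool = False,
    top_n_plot: int = 5,
) -> tuple[list[EnrichmentRow], dict[str, list[EnrichmentRow]]]:
    """Hypergeometric enrichment with per-namespace BH correction.

    Accessions outside the universe are dropped (logged).  Terms with zero
    overlap are excluded.  Returns all rows sorted by (q, p) and, per
    namespace, the ``top_n_plot`` best rows as bar-plot data.
    """
    accs = set(accessions)
    outside = accs - annotations.universe
    if outside:
        logger.warning("%d accession(s) outside the universe dropped: %s",
                       len(outside), sorted(outside)[:5])
        accs &= annotations.universe

    N = len(annotations.universe)
    n = len(accs)
    rows: list[EnrichmentRow] = []
    if n == 0:
        return [], {}

    by_ns: dict[str, list[EnrichmentRow]] = {}
    for ns in sorted({*annotations.term_namespace.values()}):
        terms = sorted(t for t, tn in annotations.term_namespace.items() if tn == ns)
        pend: list[EnrichmentRow] = []
        for t in terms:
            members = annotations.term_members.get(t, frozenset())
            k = len(members & accs)
            if k == 0:
                continue
            K = len(members)
            k_eff = max(k - 1, 0) if ease else k
            p = hypergeom_p(N, K, n, k_eff) if k_eff > 0 else 1.0
            pend.append(EnrichmentRow(t, ns, k, n, K, N, p, q=1.0, significant=False))
        if not pend:
            continue
        qs = bh_adjust([r.p for r in pend])
        for r, q in zip(pend, qs):
            r.q = float(q)
            r.significant = r.q < q_threshold
        by_ns[ns] = sorted(pend, key=lambda r: (r.q, r.p, r.term))
        rows.extend(pend)

    rows.sort(key=lambda r: (r.q, r.p, r.term))
    plot_data = {ns: lst[:top_n_plot] for ns, lst in by_ns.items()}
    return rows, plot_data


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "namespace": r.namespace, "k": r.k, "n": r.n,
             "K": r.K, "N": r.N, "p": r.p, "q": r.q, "significant": r.significant}
            for r in rows
        ]
    )


def plot_enrichment(plot_data: Mapping[str, Sequence[EnrichmentRow]],
                    out_dir: str | Path) -> list[Path]:
    """Write one horizontal bar plot (-log10 q) per namespace."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ns, rows in plot_data.items():
        if not rows:
            continue
        fig, ax = plt.subplots(figsize=(6, 0.6 * len(rows) + 1.2))
        terms = [r.term for r in rows][::-1]
        vals = [-np.log10(max(r.q, 1e-300)) for r in rows][::-1]
        ax.barh(terms, vals)
        ax.set_xlabel("-log10 q")
        ax.set_title(f"Top enriched terms ({ns})")
        fig.tight_layout()
        p = out_dir / f"enrichment_{ns}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
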