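"""Pathway over-representation analysis (ORA) on user-supplied gene sets.

A methodological stand-in for web-service pathway analysis: each pathway
is tested with a one-sided hypergeometric upper tail against the
in-experiment background (all proteins carrying a quantified
glycopeptiform, by default), with Benjamini-Hochberg q-values across the
tested pathways and a q < 1e-3 enrichment call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwaySet",
    "read_gmt",
    "ora_hypergeometric",
    "split_hit_lists",
]


@dataclass(frozen=True)
class PathwaySet:
    """One pathway: id, human-readable name, member accessions."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


def read_gmt(path) -> list[PathwaySet]:
    """Read a GMT file (tab-separated: id, description, members...)."""
    pathways: list[PathwaySet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln in fh:
            parts = [p.strip() for p in ln.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            members = frozenset(p for p in parts[2:] if p)
            if members:
                pathways.append(PathwaySet(parts[0], parts[1], members))
    if not pathways:
        raise ValueError(f"no pathways parsed from {path}")
    return pathways


def ora_hypergeometric(
    hits: set[str],
    background: set[str],
    pathways: list[PathwaySet],
    q_max: float = 1e-3,
) -> pd.DataFrame:
    """One-sided hypergeometric ORA with BH correction.

    ``hits`` must be a subset of ``background``; pathway member sets are
    intersected with the background before testing.  Returns a frame
    sorted by p with columns pathway_id, name, pathway_size (in
    background), overlap, p, q, enriched (q < ``q_max``).
    """
    if not background:
        raise ValueError("empty background universe")
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    M, N = len(background), len(hits)
    rows = []
    for pw in pathways:
        members = pw.members & background
        if not members:
            continue
        k = len(hits & members)
        n = len(members)
        # upper tail: P(X >= k)
        p = 1.0 if N == 0 else float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((pw.pathway_id, pw.name, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway_id", "name", "pathway_size", "overlap", "p"])
    if out.empty:
        out["q"] = []
        out["enriched"] = []
        return out
    out["q"] = multipletests(out["p"].to_numpy(float), method="fdr_bh")[1]
    out["enriched"] = out["q"] < q_max
    return out.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)


def split_hit_lists(results: pd.DataFrame) -> dict[str, set[str]]:
    """Partition rate-significant features into four accession lists.

    Splits by modification class (glycation vs glycosylation) and by
    direction of the rate-of-change effect (up/down in decliners);
    duplicate accessions collapse to unique sets.
    """
    need = {"sig_rate", "rate_effect", "mod_class", "protein_accession"}
    missing = need - set(results.columns)
    if missing:
        raise ValueError(f"results lack columns {sorted(missing)}")
    sig = results[results["sig_rate"].astype(bool)]
    out: dict[str, set[str]] = {
        "glycation_up": set(),
        "glycation_down": set(),
        "glycosylation_up": set(),
        "glycosylation_down": set(),
    }
    for _, row in sig.iterrows():
        direction = "up" if row["rate_effect"] >= 0 else "down"
        key = f"{row['mod_class']}_{direction}"
        if key in out:
            out[key].add(str(row["protein_accession"]))
    return out
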