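"""Mouse-to-human ortholog resolution.

Annotation services often return several human candidates per mouse gene
with a high/low orthology-confidence flag and a homology percentage. One
candidate is selected per mouse gene by a fixed rule cascade:

1. if any high-confidence candidate exists, restrict to those;
2. keep the candidate(s) with the highest homology percentage
   (compared at 4 decimal places to avoid float-noise nondeterminism);
3. among remaining ties, prefer candidates whose gene symbols match
   case-insensitively (human FILIP1L vs mouse Filip1l);
4. if ties still remain, all survivors are kept as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["OrthologMap", "resolve_orthologs"]

RESOLUTION_RULES = ("high-conf-max-homology", "max-homology", "symbol-match", "all-kept")


@dataclass
class OrthologMap:
    """Resolved mouse -> human gene pairs.

    ``pairs`` has one row per retained pair with columns mouse_gene,
    human_gene, confidence, homology_pct, resolution_rule.
    """

    pairs: pd.DataFrame

    def human_genes(self, mouse_gene: str) -> list[str]:
        sub = self.pairs[self.pairs["mouse_gene"] == mouse_gene]
        return list(sub["human_gene"])

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for row in self.pairs.itertuples(index=False):
            out.setdefault(row.mouse_gene, []).append(row.human_gene)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def resolve_orthologs(candidates: pd.DataFrame) -> OrthologMap:
    """Apply the four-rule cascade per mouse gene.

    ``candidates`` columns: mouse_gene, human_gene, confidence
    ('high'/'low'), homology_pct. Mouse genes with no candidates are
    simply absent from the result. The output is independent of input row
    order (rows are sorted before processing and ties keep all members).
    """
    required = ["mouse_gene", "human_gene", "confidence", "homology_pct"]
    missing = [c for c in required if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    df = candidates.drop_duplicates().copy()
    df["homology_r"] = df["homology_pct"].round(4)

    rows = []
    for mouse_gene, sub in df.sort_values(["mouse_gene", "human_gene"]).groupby(
        "mouse_gene", sort=True
    ):
        high = sub[sub["confidence"] == "high"]
        pool = high if len(high) else sub
        used_high = len(high) > 0
        best = pool["homology_r"].max()
        pool = pool[pool["homology_r"] == best]
        rule = "high-conf-max-homology" if used_high else "max-homology"
        if len(pool) > 1:
            symbol_match = pool[
                pool["human_gene"].str.lower() == str(mouse_gene).lower()
            ]
            if len(symbol_match):
                pool = symbol_match
                rule = "symbol-match"
            elif len(pool) > 1:
                rule = "all-kept"
        if len(pool) > 1 and rule != "all-kept":
            rule = "all-kept"
        for r in pool.itertuples(index=False):
            rows.append(
                {
                    "mouse_gene": mouse_gene,
                    "human_gene": r.human_gene,
                    "confidence": r.confidence,
                    "homology_pct": r.homology_pct,
                    "resolution_rule": rule,
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["mouse_gene", "human_gene", "confidence", "homology_pct", "resolution_rule"]
    )
    return OrthologMap(pairs=pairs)
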