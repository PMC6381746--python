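"""Run summaries and positional gene annotation of significant windows.

Coordinates are 0-based half-open internally; BED input is taken as-is
and GFF3 (1-based, closed) is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import (WindowResult, compute_h2_snp,
                      windows_for_variance_fraction)

__all__ = ["RunSummary", "summarize_run", "annotate_windows",
           "read_gene_table"]


@dataclass
class RunSummary:
    trait: str
    prior: str
    dependent: str                   # "phenotype" | "debv"
    sigma2_snp: float
    sigma2_e: float
    h2_snp: float
    additive_proportion: float | None
    windows_to_10pct: int
    reached_10pct: bool

    def format_h2_snp(self) -> str:
        s = f"{self.h2_snp:.3f}"
        if self.additive_proportion is not None:
            s += f" [{self.additive_proportion:.3f}]"
        return s

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "prior": self.prior,
            "dependent": self.dependent,
            "sigma2_snp": round(self.sigma2_snp, 3),
            "sigma2_e": round(self.sigma2_e, 3),
            "h2_snp": self.format_h2_snp(),
            "windows_to_10pct": self.windows_to_10pct,
        }


def summarize_run(posterior, window_results: list[WindowResult], h2: float,
                  dependent: str, trait: str = "trait") -> RunSummary:
    """Assemble the variance-component summary for one model fit."""
    s2_snp = posterior.sigma2_snp
    s2_e = posterior.sigma2_e
    h2s = compute_h2_snp(s2_snp, s2_e, dependent, h2)
    count = windows_for_variance_fraction(window_results, 0.10)
    return RunSummary(
        trait=trait,
        prior=posterior.spec.prior,
        dependent=dependent,
        sigma2_snp=s2_snp,
        sigma2_e=s2_e,
        h2_snp=h2s.h2_snp,
        additive_proportion=h2s.additive_proportion,
        windows_to_10pct=count.count,
        reached_10pct=count.reached,
    )


def read_gene_table(path: str) -> pd.DataFrame:
    """Read a gene annotation as BED (chrom start end name) or GFF3.

    Returns columns ``chrom`` (int), ``start``, ``end`` (0-based half-open),
    ``name``. Malformed lines are reported with their line numbers.
    """
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3"))
    rows, bad = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    chrom = int(parts[0])
                    start = int(parts[3]) - 1          # 1-based closed -> half-open
                    end = int(parts[4])
                    name = _gff_attr(parts[8], ("Name", "ID")) or f"line{ln}"
                    feature = parts[2]
                    if feature not in ("gene", "pseudogene", "ncRNA_gene"):
                        continue
                else:
                    if len(parts) < 3:
                        raise ValueError("fewer than 3 BED columns")
                    chrom = int(parts[0])
                    start = int(parts[1])
                    end = int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"line{ln}"
                if end <= start:
                    raise ValueError("end <= start")
            except ValueError as exc:
                bad.append(f"line {ln}: {exc}")
                continue
            rows.append((chrom, start, end, name))
    if bad:
        raise ValueError("malformed annotation lines:\n" + "\n".join(bad))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _gff_attr(attrs: str, keys) -> str | None:
    fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def annotate_windows(windows: list[WindowResult],
                     genes: pd.DataFrame) -> pd.DataFrame:
    """Join windows with genes overlapping them (half-open intervals).

    A gene overlaps a window when gene.start < window.end and
    gene.end > window.start on the same chromosome.
    """
    gchrom = genes["chrom"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    gname = genes["name"].to_numpy()
    rows = []
    for r in windows:
        w = r.window
        hit = (gchrom == w.chrom) & (gstart < w.end) & (gend > w.start)
        names = gname[hit]
        rows.append({
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "pct_var": r.pct_var,
            "n_genes": int(hit.sum()),
            "genes": ";".join(map(str, names)),
        })
    return pd.DataFrame(rows)
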