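"""Human-readable reports and the combined marker panel export.

Every report carries a provenance header (tool version, parameters, input
checksums) so a run can be traced; timestamps are deliberately omitted so
identical inputs give byte-identical report bodies.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence

from .io_formats import Contig, atomic_open, file_md5


def provenance_lines(tool: str, params: Mapping = None, inputs: Sequence = ()) -> List[str]:
    from . import __version__

    lines = [f"estpoly {__version__} {tool}"]
    for k, v in sorted((params or {}).items()):
        lines.append(f"param {k}={v}")
    for p in inputs:
        lines.append(f"input {os.path.basename(os.fspath(p))} md5={file_md5(p)}")
    return lines


def write_tsv_report(df, path, header_lines: Sequence[str] = (), footer_lines: Sequence[str] = ()) -> None:
    with atomic_open(path) as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(df.to_csv(sep="\t", index=False))
        for line in footer_lines:
            fh.write(f"# {line}\n")


def _flanks(contig: Contig, start: int, end: int, flank: int = 100):
    left = contig.sequence[max(0, start - flank) : start]
    right = contig.sequence[end : end + flank]
    return left, right


def report_marker_panel(
    snps,
    ssrs,
    polyssr_df,
    contigs: Sequence[Contig],
    flank: int = 100,
):
    """Combined candidate-marker table with flanking sequence for primer design.

    One row per marker (SNP / SSR / polymorphic SSR) with up to ``flank`` nt
    of sequence on each side (capped at what the contig offers).  Returns
    ``(DataFrame, footer_counts)``.
    """
    import pandas as pd

    by_id = {c.id: c for c in contigs}
    rows = []
    for s in snps:
        c = by_id[s.contig_id]
        left, right = _flanks(c, s.pos, s.pos + 1, flank)
        rows.append(
            {
                "marker_type": "SNP",
                "contig": s.contig_id,
                "start": s.pos + 1,
                "end": s.pos + 1,
                "detail": f"{s.allele_major}/{s.allele_minor};{s.tstv};{s.class_code}",
                "left_flank": left,
                "right_flank": right,
            }
        )
    for s in ssrs:
        c = by_id[s.contig_id]
        left, right = _flanks(c, s.start, s.end, flank)
        rows.append(
            {
                "marker_type": "SSR",
                "contig": s.contig_id,
                "start": s.start + 1,
                "end": s.end,
                "detail": f"({s.motif}){s.repeats};{s.ssr_class}",
                "left_flank": left,
                "right_flank": right,
            }
        )
    if polyssr_df is not None:
        for _, r in polyssr_df.iterrows():
            c = by_id[r["contig"]]
            left, right = _flanks(c, int(r["ssr_start"]) - 1, int(r["ssr_end"]), flank)
            rows.append(
                {
                    "marker_type": "polySSR",
                    "contig": r["contig"],
                    "start": int(r["ssr_start"]),
                    "end": int(r["ssr_end"]),
                    "detail": f"({r['motif']});diff={r['allele_diff_nt']}nt;{r['carriers']}",
                    "left_flank": left,
                    "right_flank": right,
                }
            )
    cols = ["marker_type", "contig", "start", "end", "detail", "left_flank", "right_flank"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["contig", "start", "marker_type"], kind="stable").reset_index(drop=True)
    counts = df["marker_type"].value_counts().to_dict() if len(df) else {}
    footer = [
        f"n_snp={counts.get('SNP', 0)}",
        f"n_ssr={counts.get('SSR', 0)}",
        f"n_polyssr={counts.get('polySSR', 0)}",
    ]
    return df, footer


def summary_report_lines(summary: Dict) -> List[str]:
    """Render snp_summaries output as aligned key/value text lines."""
    lines = []
    for key in (
        "n_snps", "ts_count", "tv_count", "ts_fraction", "n_contigs_with_snps",
        "n_contigs_multi_snp", "mean_snps_per_contig", "density_per_kb",
        "n_high_depth",
    ):
        v = summary[key]
        lines.append(f"{key}\t{v:.4f}" if isinstance(v, float) else f"{key}\t{v}")
    for code, n in sorted(summary["class_histogram"].items(), key=lambda kv: -kv[1]):
        lines.append(f"class\t{code}\t{n}")
    for sample, buckets in sorted(summary["per_sample_rollup"].items()):
        lines.append(
            f"rollup\t{sample}\tM={buckets['M']}\tP={buckets['P']}\tM+P={buckets['M+P']}"
        )
    return lines
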