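"""High-level orchestration: simulate -> type -> features -> structure -> report.

Each step reads and writes the plain-text formats of the I/O modules, so the
command-line interface stays a thin wrapper and every intermediate artifact
is inspectable.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .features import build_feature_table
from .germline import GermlineDb, TypedRecord, type_repertoire
from .io import apply_count_filter, deduplicate_aa, write_airr_table
from .records import RegionAnnotation, VhhRecord
from .stats import (
    interface_summary_frame,
    summarize_by_type,
    summarize_interfaces,
)
from .structure import (
    ComplexStructure,
    epitope_size_filter,
    fr2_cdr3_interaction_map,
    parse_complex,
    summarize_complex,
)
from .synth import (
    RepertoireConfig,
    SYNTHETIC_HINGE_MOTIFS,
    generate_germline_db,
    generate_repertoire,
    generate_toy_complex_set,
)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_sequences": 2000,
    "shm_rate": 0.03,
    "n_complexes": 60,
    "min_count": 5,
    "cutoff": 4.0,
    "min_epitope": 8,
    "trim": 2,
    "pka_set": "IPC_protein",
    "sasa_points": 240,
}


def typing_frame(typed: Sequence[TypedRecord]) -> pd.DataFrame:
    """Per-record typing table (one row per repertoire entry)."""
    rows = []
    for t in typed:
        rows.append({
            "sequence_id": t.record.id,
            "classical": t.assignment.classical,
            "rule": t.assignment.rule,
            "vhh_type": t.assignment.vhh_type,
            "residue42": t.assignment.residue42,
            "n_cys": t.assignment.n_cys,
            "germline": t.hit.gene_name if t.hit else "",
            "mismatches": t.hit.mismatches if t.hit else math.nan,
            "mismatch_score": t.hit.mismatch_score if t.hit else math.nan,
            "hinge": t.hinge,
            "fr4_arg": t.fr4_arg,
            "fr4_codon": t.fr4_codon or "",
            "animal_id": t.record.animal_id,
            "age_group": t.record.age_group or "",
            "count": t.record.count,
        })
    return pd.DataFrame(rows)


def simulate(config: dict, outdir: str | Path) -> dict:
    """Generate a repertoire + toy structure set under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_CONFIG, **config}
    rep_cfg = RepertoireConfig(
        n_sequences=cfg["n_sequences"], shm_rate=cfg["shm_rate"], seed=cfg["seed"]
    )
    records, annotations, truth = generate_repertoire(rep_cfg)
    write_airr_table(zip(records, annotations), outdir / "repertoire.airr.tsv")
    truth.to_csv(outdir / "repertoire.truth.tsv", sep="\t", index=False)
    db = generate_germline_db(cfg["seed"])
    with open(outdir / "germlines.fasta", "w") as fh:
        for entry in db.entries:
            fh.write(f">{entry.gene_name}\n{entry.nt_seq}\n")
    (outdir / "whitelist.txt").write_text("\n".join(sorted(db.vhh_whitelist)) + "\n")

    pdb_dir = outdir / "complexes"
    pdb_dir.mkdir(exist_ok=True)
    labeled = generate_toy_complex_set(cfg["n_complexes"], seed=cfg["seed"], outdir=pdb_dir)
    manifest_rows, region_rows = [], []
    for vhh_type, truth_cx in labeled:
        row = dict(truth_cx.manifest)
        row["vhh_type"] = vhh_type
        manifest_rows.append(row)
        for resnum, (region, imgt) in truth_cx.structure.antibody_region_map.items():
            region_rows.append({
                "complex_id": truth_cx.structure.complex_id,
                "resnum": resnum, "region": region, "imgt": imgt or "",
            })
    pd.DataFrame(manifest_rows).to_csv(outdir / "complexes.manifest.tsv", sep="\t", index=False)
    pd.DataFrame(region_rows).to_csv(outdir / "complexes.regions.tsv", sep="\t", index=False)
    return {"n_records": len(records), "n_complexes": len(labeled), "outdir": str(outdir)}


def run_typing(
    items: Sequence[tuple[VhhRecord, RegionAnnotation]],
    db: GermlineDb,
    min_count: int = 5,
    hinge_db: Optional[dict] = None,
) -> tuple[list[TypedRecord], pd.DataFrame]:
    """Count filter -> amino-acid dedup -> typing; returns objects + table."""
    records = apply_count_filter([r for r, _ in items], min_count)
    ann = {r.id: a for r, a in items}
    records = deduplicate_aa(records)
    typed = type_repertoire(
        [(r, ann[r.id]) for r in records], db,
        hinge_db=hinge_db or SYNTHETIC_HINGE_MOTIFS,
    )
    return typed, typing_frame(typed)


def load_complexes(
    manifest: pd.DataFrame, regions: pd.DataFrame
) -> list[ComplexStructure]:
    """Parse every complex in a manifest, attaching its region map."""
    region_maps: dict[str, dict] = {}
    for _, row in regions.iterrows():
        region_maps.setdefault(str(row["complex_id"]), {})[str(row["resnum"])] = (
            row["region"],
            str(row["imgt"]) if str(row.get("imgt", "")) not in ("", "nan") else None,
        )
    out = []
    for _, row in manifest.iterrows():
        out.append(
            parse_complex(
                row["pdb_path"],
                antibody_chain=row["antibody_chain"],
                antigen_chains=set(str(row["antigen_chains"]).split(",")),
                complex_id=str(row["complex_id"]),
                antibody_region_map=region_maps.get(str(row["complex_id"]), {}),
            )
        )
    return out


def run_structure_analysis(
    structures: Sequence[ComplexStructure],
    types: Optional[dict[str, str]] = None,
    cutoff: float = 4.0,
    min_epitope: int = 8,
    trim: int = 2,
    sasa_points: int = 240,
) -> dict:
    """Interface summaries, epitope filter, interaction map and tables."""
    summaries = [
        summarize_complex(cs, cutoff=cutoff, n_points=sasa_points, trim=trim)
        for cs in structures
    ]
    kept = epitope_size_filter(summaries, min_epitope)
    kept_ids = {s.complex_id for s in kept}
    frame = interface_summary_frame(kept, types)
    tables = summarize_interfaces(frame) if len(frame) else {}
    imap = fr2_cdr3_interaction_map(
        [cs for cs in structures if cs.complex_id in kept_ids], cutoff
    )
    return {
        "summaries": summaries,
        "kept": kept,
        "frame": frame,
        "tables": tables,
        "interaction_map": imap,
    }


def write_report(
    outdir: str | Path,
    typing_df: pd.DataFrame,
    feature_df: pd.DataFrame,
    structure_results: Optional[dict] = None,
) -> dict:
    """Write all table analogs as TSV plus a single stats JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged = typing_df.merge(feature_df, on="sequence_id", how="left")
    tables = summarize_by_type(merged)
    stats_json: dict = {"n_sequences": int(len(merged))}
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t")
        stats_json[name] = json.loads(table.to_json(orient="index"))
    if structure_results is not None:
        structure_results["frame"].drop(columns=["fr2_positions"]).to_csv(
            outdir / "interface_summaries.tsv", sep="\t", index=False
        )
        structure_results["interaction_map"].to_csv(
            outdir / "fr2_cdr3_interaction_map.tsv", sep="\t"
        )
        st = structure_results["tables"]
        for key in ("contact_counts", "fr2_position_usage", "fr2_top3"):
            if key in st and len(st[key]):
                st[key].to_csv(outdir / f"{key}.tsv", sep="\t")
        if "fr2_involving_pct" in st:
            st["fr2_involving_pct"].to_csv(outdir / "fr2_involving_pct.tsv", sep="\t")
            stats_json["fr2_involving_pct"] = st["fr2_involving_pct"].to_dict()
        if "paratope_kind_comparisons" in st:
            stats_json["paratope_kind_comparisons"] = {
                k: {"statistic": c.statistic, "p_value": c.p_value, "stars": c.stars}
                for k, c in st["paratope_kind_comparisons"].items()
            }
        if "contact_correlations" in st:
            stats_json["contact_correlations"] = {
                t: json.loads(m.to_json(orient="index"))
                for t, m in st["contact_correlations"].items()
            }
    stats_json["footer"] = "raw P-values; no multiple-testing correction applied"
    (outdir / "stats.json").write_text(json.dumps(stats_json, indent=2, default=str))
    return stats_json


def run_all(config: dict, outdir: str | Path) -> dict:
    """End-to-end: simulate -> type -> features -> structure -> report."""
    from .io import read_airr_table

    outdir = Path(outdir)
    cfg = {**DEFAULT_CONFIG, **config}
    simulate(cfg, outdir)
    items = read_airr_table(outdir / "repertoire.airr.tsv")
    db = generate_germline_db(cfg["seed"])
    typed, typing_df = run_typing(items, db, min_count=cfg["min_count"])
    feature_df = build_feature_table(
        [(t.record, t.annotation) for t in typed], pka_set=cfg["pka_set"]
    )
    typing_df.to_csv(outdir / "typing.tsv", sep="\t", index=False)
    feature_df.to_csv(outdir / "features.tsv", sep="\t", index=False)
    manifest = pd.read_csv(outdir / "complexes.manifest.tsv", sep="\t")
    regions = pd.read_csv(outdir / "complexes.regions.tsv", sep="\t", dtype=str)
    structures = load_complexes(manifest, regions)
    types = dict(zip(manifest["complex_id"].astype(str), manifest["vhh_type"]))
    structure_results = run_structure_analysis(
        structures,
        types,
        cutoff=cfg["cutoff"],
        min_epitope=cfg["min_epitope"],
        trim=cfg["trim"],
        sasa_points=cfg["sasa_points"],
    )
    report = write_report(outdir / "report", typing_df, feature_df, structure_results)
    return {
        "typing": typing_df,
        "features": feature_df,
        "structure": structure_results,
        "report": report,
    }
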