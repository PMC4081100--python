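"""Readers and writers for the pipeline's tab-separated exchange formats.

All formats are plain text: probe tables, target sets, DE sets, curated
interactions, ortholog maps, module and GO files, BED-like hit tables and
promoter FASTA.  Coordinates in hit tables are 0-based from the promoter
5' end; genomic intervals in FASTA headers are 1-based inclusive.
"""

from __future__ import annotations

import pandas as pd

from .coexpression import DESet
from .footprint import Footprint, OrthologGroup
from .promoters import MotifHit, Promoter, TargetSet

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "write_promoters_fasta",
    "write_hits",
    "write_target_sets",
    "read_target_sets",
    "read_de_sets",
    "read_curated_pairs",
    "read_parent_map",
    "write_parent_map",
    "read_module_files",
    "write_module_files",
    "write_ortholog_fastas",
    "read_ortholog_fastas",
    "write_footprints",
]


def read_probe_table(path) -> dict[str, list["object"]]:
    """Probe TSV -> per-TF, per-replicate experiment lists.

    Columns: probe_id, sequence, intensity, replicate and optionally tf_id
    (single-TF files may omit it; the TF is then the file's stem).
    """
    from pathlib import Path

    from .pbm import PBMExperiment, ProbeRecord

    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "sequence", "intensity", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "tf_id" not in df.columns:
        df["tf_id"] = Path(path).stem
    out: dict[str, list] = {}
    for (tf, rep), grp in df.groupby(["tf_id", "replicate"], sort=True):
        probes = [
            ProbeRecord(str(r.probe_id), str(r.sequence), float(r.intensity), int(rep))
            for r in grp.itertuples()
        ]
        out.setdefault(str(tf), []).append(
            PBMExperiment(tf_id=str(tf), probes=probes, n_replicates=1)
        )
    return out


def write_probe_table(experiments: dict[str, list], path) -> None:
    rows = []
    for tf in sorted(experiments):
        for exp in experiments[tf]:
            for p in exp.probes:
                rows.append((tf, p.probe_id, p.sequence, p.intensity, p.replicate))
    pd.DataFrame(
        rows, columns=["tf_id", "probe_id", "sequence", "intensity", "replicate"]
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_promoters_fasta(promoters: list[Promoter], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(promoters, key=lambda x: x.gene_id):
            fh.write(
                f">{p.gene_id} {p.chromosome}:{p.start}-{p.end}({p.strand})\n"
            )
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i : i + 80] + "\n")


def write_hits(hits: list[MotifHit], path) -> None:
    """BED-like 6 columns, promoter-relative: gene, start, end, pattern, conserved, strand."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tstart\tend\tpattern\tconserved\tstrand\n")
        for h in sorted(hits, key=lambda x: (x.gene_id, x.offset, x.pattern)):
            fh.write(
                f"{h.gene_id}\t{h.offset}\t{h.end}\t{h.pattern}\t{int(h.conserved)}\t{h.strand}\n"
            )


def write_target_sets(sets: list[TargetSet], path) -> None:
    rows = [
        (ts.tf_id, gene, ts.tier)
        for ts in sorted(sets, key=lambda s: (s.tf_id, s.tier))
        for gene in sorted(ts.genes)
    ]
    pd.DataFrame(rows, columns=["tf_id", "gene_id", "tier"]).to_csv(
        path, sep="\t", index=False
    )


def read_target_sets(path) -> list[TargetSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (tf, tier), grp in df.groupby(["tf_id", "tier"], sort=True):
        out.append(TargetSet(tf_id=str(tf), tier=str(tier), genes=set(grp["gene_id"])))
    return out


def read_de_sets(path) -> dict[str, DESet]:
    """Two-column TSV (tf_id, gene_id) -> DE sets per TF."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(tf): DESet(tf_id=str(tf), genes=set(grp["gene_id"]))
        for tf, grp in df.groupby("tf_id", sort=True)
    }


def read_curated_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return [(str(a), str(b)) for a, b in zip(df[cols[0]], df[cols[1]])]


def read_parent_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term, parent) -> term -> set of parents."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for term, parent in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(term), set()).add(str(parent))
    return out


def write_parent_map(parent_map: dict[str, set[str]], path) -> None:
    rows = [
        (term, parent)
        for term in sorted(parent_map)
        for parent in sorted(parent_map[term])
    ]
    pd.DataFrame(rows, columns=["term", "parent"]).to_csv(path, sep="\t", index=False)


def read_module_files(gene_path, go_path) -> list:
    """(module_id, gene_id) and (module_id, go_term) TSVs -> modules."""
    from .network import FunctionalModule

    genes = pd.read_csv(gene_path, sep="\t")
    gos = pd.read_csv(go_path, sep="\t")
    go_map: dict[str, set[str]] = {}
    for mid, term in zip(gos.iloc[:, 0], gos.iloc[:, 1]):
        go_map.setdefault(str(mid), set()).add(str(term))
    out = []
    for mid, grp in genes.groupby(genes.columns[0], sort=True):
        out.append(
            FunctionalModule(
                module_id=str(mid),
                genes=set(map(str, grp.iloc[:, 1])),
                go_terms=go_map.get(str(mid), set()),
            )
        )
    return out


def write_module_files(modules: list, gene_path, go_path) -> None:
    gene_rows, go_rows = [], []
    for mod in sorted(modules, key=lambda m: m.module_id):
        gene_rows += [(mod.module_id, g) for g in sorted(mod.genes)]
        go_rows += [(mod.module_id, t) for t in sorted(mod.go_terms)]
    pd.DataFrame(gene_rows, columns=["module_id", "gene_id"]).to_csv(
        gene_path, sep="\t", index=False
    )
    pd.DataFrame(go_rows, columns=["module_id", "go_term"]).to_csv(
        go_path, sep="\t", index=False
    )


def write_ortholog_fastas(groups: dict[str, OrthologGroup], map_path, fasta_dir) -> None:
    """Ortholog map TSV (query_gene, species, ortholog_gene) + per-species FASTA."""
    from pathlib import Path

    fasta_dir = Path(fasta_dir)
    fasta_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    handles: dict[str, list[str]] = {}
    for gene in sorted(groups):
        for sp in groups[gene].species:
            ortho_id = f"{gene}_{sp}"
            rows.append((gene, sp, ortho_id))
            handles.setdefault(sp, []).append(
                f">{ortho_id}\n{groups[gene].promoters[sp]}\n"
            )
    pd.DataFrame(rows, columns=["query_gene", "species", "ortholog_gene"]).to_csv(
        map_path, sep="\t", index=False
    )
    for sp, lines in sorted(handles.items()):
        with open(fasta_dir / f"{sp}.fasta", "w") as fh:
            fh.writelines(lines)


def read_ortholog_fastas(map_path, fasta_dir) -> dict[str, OrthologGroup]:
    from pathlib import Path

    from pyfaidx import Fasta

    df = pd.read_csv(map_path, sep="\t")
    fasta_dir = Path(fasta_dir)
    seqs: dict[str, Fasta] = {}
    groups: dict[str, dict[str, str]] = {}
    for q, sp, oid in zip(df["query_gene"], df["species"], df["ortholog_gene"]):
        sp = str(sp)
        if sp not in seqs:
            seqs[sp] = Fasta(str(fasta_dir / f"{sp}.fasta"), as_raw=True,
                             sequence_always_upper=True)
        groups.setdefault(str(q), {})[sp] = str(seqs[sp][str(oid)][:])
    return {
        q: OrthologGroup(query_gene=q, promoters=proms)
        for q, proms in sorted(groups.items())
    }


def write_footprints(per_gene: dict[str, list[Footprint]], path) -> None:
    """BED-like intervals with support level and FDR columns."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tstart\tend\tlevel\tlength\tfdr\n")
        for gene in sorted(per_gene):
            for fp in sorted(per_gene[gene], key=lambda f: (f.start, f.level)):
                fdr = "NA" if fp.fdr is None else f"{fp.fdr:.4f}"
                fh.write(f"{gene}\t{fp.start}\t{fp.end}\t{fp.level}\t{fp.length}\t{fdr}\n")
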