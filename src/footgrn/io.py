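"""Readers and writers for the pipeline's file formats.

All genomic coordinates are 0-based half-open (BED native).  Cut
profiles are stored as one bedGraph per strand; motif libraries as
JASPAR-format PFM files (via Bio.motifs); the condensed catalog as a TSV
with one family per row (family_id, representative_motif,
semicolon-separated member TF genes).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from footgrn.motifs import PWM, MotifFamily
from footgrn.simulate import Annotation, PlantedTruth, StrandedCutProfile

# ---------------------------------------------------------------- FASTA


def write_fasta(genome: dict[str, str] | Annotation, path, width: int = 60) -> None:
    seqs = genome.sequences() if isinstance(genome, Annotation) else genome
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = str(seqs[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ------------------------------------------------------------- bedGraph


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Run-length-compressed bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            if chrom in track:
                track[chrom][int(s):int(e)] = int(float(v))
    return track


def write_profile(profile: StrandedCutProfile, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    fwd_path = prefix.with_suffix(".fwd.bedGraph")
    rev_path = prefix.with_suffix(".rev.bedGraph")
    write_bedgraph(profile.fwd, fwd_path)
    write_bedgraph(profile.rev, rev_path)
    return fwd_path, rev_path


def read_profile(sample_id: str, fwd_path, rev_path, chrom_lengths: dict[str, int]) -> StrandedCutProfile:
    return StrandedCutProfile(
        sample_id,
        read_bedgraph(fwd_path, chrom_lengths),
        read_bedgraph(rev_path, chrom_lengths),
    )


# ------------------------------------------------------------ BED / BEDPE


def write_bed6(df: pd.DataFrame, path) -> None:
    """Columns used: chrom, start, end, name, score (default 0), strand (default '.')."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df["name"],
        "score": df.get("score", pd.Series(0, index=df.index)),
        "strand": df.get("strand", pd.Series(".", index=df.index)),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )


def write_bedpe(interactions: pd.DataFrame, path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    out = interactions[cols].copy()
    out["name"] = interactions.get("name", ".")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :7] if df.shape[1] >= 7 else df.iloc[:, :6]
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"][: df.shape[1]]
    df.columns = names
    return df


# ---------------------------------------------------------------- JASPAR


def write_jaspar(pwms: list[PWM], path, scale: int = 100) -> None:
    """JASPAR-format PFM file (probabilities scaled to integer counts)."""
    records = []
    for p in pwms:
        counts = {
            base: [float(round(p.matrix[i, bi] * scale, 4)) for i in range(p.length)]
            for bi, base in enumerate("ACGT")
        }
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = p.name
        m.name = p.name
        records.append(m)
    text = bio_motifs.write(records, "jaspar")
    Path(path).write_text(text)


def read_jaspar(path) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
            name = m.name or m.matrix_id
            out.append(PWM.from_counts(str(name), counts, source="jaspar"))
    return out


def read_tf_annotation(path) -> dict[str, list[str]]:
    """TSV motif_name <tab> semicolon-separated TF gene symbols."""
    df = pd.read_csv(path, sep="\t", header=None, names=["motif", "genes"], comment="#")
    return {
        str(r.motif): [g for g in str(r.genes).split(";") if g]
        for r in df.itertuples()
    }


def write_tf_annotation(annotation: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for motif in sorted(annotation):
            fh.write(f"{motif}\t{';'.join(annotation[motif])}\n")


# ----------------------------------------------------------- catalog TSV


def write_catalog_tsv(families: list[MotifFamily], path) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "representative_motif": f.representative.name,
            "member_tf_genes": ";".join(f.member_tf_genes),
        }
        for f in families
    ]
    pd.DataFrame(rows, columns=["family_id", "representative_motif", "member_tf_genes"]).to_csv(
        path, sep="\t", index=False
    )


def read_catalog_tsv(path) -> list[dict]:
    """Parse a condensed-catalog TSV; raises with the offending line number."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"family_id", "member_tf_genes"}
        if not required <= set(header):
            raise ValueError(f"{path}: line 1: missing columns {sorted(required - set(header))}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(required):
                raise ValueError(f"{path}: line {lineno}: expected >= {len(required)} fields")
            try:
                genes = [g for g in parts[idx["member_tf_genes"]].split(";") if g]
            except IndexError:
                raise ValueError(f"{path}: line {lineno}: missing member_tf_genes")
            records.append({
                "family_id": parts[idx["family_id"]],
                "representative_motif": parts[idx.get("representative_motif", idx["family_id"])],
                "member_tf_genes": genes,
            })
    return records


# ------------------------------------------------------------ truth JSON


def write_truth_json(truth: PlantedTruth, path) -> None:
    from dataclasses import asdict

    payload = {
        "config": asdict(truth.config),
        "peaks": truth.peaks.to_dict(orient="records"),
        "footprints": truth.footprints.to_dict(orient="records"),
        "edges": truth.edges.to_dict(orient="records"),
        "links": truth.links.to_dict(orient="records"),
        "interactions": truth.interactions.to_dict(orient="records"),
        "families": truth.families,
        "tf_annotation": truth.tf_annotation,
        "upregulated": truth.upregulated,
        "source_families": truth.source_families,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# -------------------------------------------------------------- genes TSV


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_newick(linkage_matrix: np.ndarray, labels: list[str], path) -> None:
    """Dendrogram as a newick string with branch lengths from merge heights."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(linkage_matrix)

    def render(node, parent_height):
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    Path(path).write_text(render(tree, tree.dist) + ";\n")
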