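"""Readers and writers for the pipeline's standard formats.

FASTA/FASTQ parsing goes through Biopython (gzip handled transparently);
tables are tab-separated without quoting, '.' for missing values, ordered
deterministically (gene id, then rank) so reruns are byte-identical.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from nadcapseq.circnc import JunctionCall
from nadcapseq.enrichment import CountMatrix
from nadcapseq.errors import FormatError
from nadcapseq.simdata import FastqRecord, TranscriptModel

MISSING = "."


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _strip_mate(read_id: str) -> str:
    head = read_id.split()[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def read_fastq_pairs(path1, path2=None) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Stream read pairs from two FASTQ files (or one interleaved file).

    Mate ids are matched after stripping '/1' / '/2' suffixes or
    Casava-style space tags; gzip input is transparent. Mismatched ids,
    unequal record counts or malformed records raise FormatError naming
    the record number.
    """

    def _records(path):
        with _open_text(path) as fh:
            try:
                for rec in SeqIO.parse(fh, "fastq"):
                    yield FastqRecord(
                        rec.description or rec.id,
                        str(rec.seq).upper(),
                        "".join(
                            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                        ),
                    )
            except ValueError as exc:
                raise FormatError(f"{path}: {exc}") from exc

    if path2 is None:
        it = _records(path1)
        n = 0
        while True:
            r1 = next(it, None)
            if r1 is None:
                return
            r2 = next(it, None)
            n += 1
            if r2 is None:
                raise FormatError(f"{path1}: odd record count at pair {n}")
            if _strip_mate(r1.read_id) != _strip_mate(r2.read_id):
                raise FormatError(f"{path1}: unpaired ids at pair {n}")
            yield r1, r2
    else:
        it1, it2 = _records(path1), _records(path2)
        n = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            n += 1
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError(f"pair files differ in record count at record {n}")
            if _strip_mate(r1.read_id) != _strip_mate(r2.read_id):
                raise FormatError(f"unpaired ids at record {n}")
            yield r1, r2


def write_fastq_pairs(pairs: Iterable[tuple[FastqRecord, FastqRecord]], path1, path2) -> None:
    """Write read pairs to two FASTQ files ('/1' and '/2' id convention)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.read_id}\n{r1.sequence}\n+\n{r1.quality}\n")
            f2.write(f"@{r2.read_id}\n{r2.sequence}\n+\n{r2.quality}\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA to an id -> sequence mapping; uppercased, U mapped to T.

    Duplicate ids raise FormatError.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if rec.id in out:
                raise FormatError(f"{path}: duplicate id {rec.id!r}")
            out[rec.id] = seq
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    """Canonical TSV dialect: tab separated, no quoting, '.' for missing."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])


def read_annotation(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"gene_id", "utr5_len", "cds_len", "utr3_len"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def models_from_reference(fasta: dict[str, str], annotation: pd.DataFrame) -> dict[str, TranscriptModel]:
    """Rebuild minimal transcript models from a reference FASTA + annotation.

    Cap-site / cleavage distributions are unknown for externally supplied
    references and left empty; the models still carry the coordinate frame
    junction calling needs.
    """
    models = {}
    for row in annotation.itertuples(index=False):
        seq = fasta.get(row.gene_id)
        if seq is None:
            raise FormatError(f"annotation gene {row.gene_id!r} absent from FASTA")
        models[row.gene_id] = TranscriptModel(
            gene_id=row.gene_id,
            sequence=seq,
            utr5_len=int(row.utr5_len),
            cds_len=int(row.cds_len),
            utr3_len=int(row.utr3_len),
            cap_site_dist_m7g=[],
            cap_site_dist_nad=[],
            cleavage_site_dist=[],
            primer_fwd=(int(getattr(row, "primer_fwd_start", 0)), int(getattr(row, "primer_fwd_end", 0))),
            primer_rev=(int(getattr(row, "primer_rev_start", 0)), int(getattr(row, "primer_rev_end", 0))),
        )
    return models


def read_count_matrix(counts_path, samples_path, lengths_path) -> CountMatrix:
    """Assemble a CountMatrix from counts, sample-sheet and gene-length TSVs.

    counts: gene_id + one column per sample; samples: sample_id,
    condition[, replicate]; lengths: gene_id, length.
    """
    counts = read_tsv(counts_path)
    samples = read_tsv(samples_path)
    lengths = read_tsv(lengths_path)
    for req, df, path in (
        ({"gene_id"}, counts, counts_path),
        ({"sample_id", "condition"}, samples, samples_path),
        ({"gene_id", "length"}, lengths, lengths_path),
    ):
        if not req <= set(df.columns):
            raise FormatError(f"{path}: missing columns {sorted(req - set(df.columns))}")
    sample_ids = list(samples["sample_id"])
    missing = set(sample_ids) - set(counts.columns)
    if missing:
        raise FormatError(f"{counts_path}: missing sample columns {sorted(missing)}")
    genes = list(counts["gene_id"])
    length_map = dict(zip(lengths["gene_id"], lengths["length"]))
    try:
        glen = [int(length_map[g]) for g in genes]
    except KeyError as exc:
        raise FormatError(f"{lengths_path}: no length for gene {exc}") from exc
    return CountMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        conditions=list(samples["condition"]),
        counts=counts[sample_ids].to_numpy().round().astype(int),
        gene_lengths=pd.Series(glen).to_numpy(),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = [
    "gene_id", "treatment", "stream", "rank", "representative_sequence",
    "count", "fraction", "cap_site_1based", "three_prime_site_1based",
    "polya_len", "ref_base", "category", "confidence", "ambiguous_alt_sites_1based",
]


def junction_report(
    calls_by_gene_treatment: dict[tuple[str, str], dict[str, list[JunctionCall]]],
    models: dict[str, TranscriptModel],
    k: int = 5,
) -> pd.DataFrame:
    """Flatten junction calls into the per-gene report table.

    One row per (gene, treatment, stream, rank <= k); coordinates are
    1-based inclusive, fractions relative to the stream's polyA-passing
    reads. Rows are ordered gene id, treatment, stream, rank.
    """
    from nadcapseq.circnc import classify_cap_site

    rows = []
    for (gene, treatment), streams in sorted(calls_by_gene_treatment.items()):
        model = models[gene]
        for stream in sorted(streams):
            ordered = sorted(
                streams[stream],
                key=lambda c: (-c.support_count, c.representative_sequence),
            )[:k]
            for rank, call in enumerate(ordered, start=1):
                if call.confidence != "none" and call.cap_site is not None:
                    cls = classify_cap_site(call, model)
                    ref_base, category = cls.ref_base, cls.category
                else:
                    ref_base, category = None, None
                rows.append(
                    {
                        "gene_id": gene,
                        "treatment": treatment,
                        "stream": stream,
                        "rank": rank,
                        "representative_sequence": call.representative_sequence,
                        "count": call.support_count,
                        "fraction": round(call.support_fraction, 6),
                        "cap_site_1based": None if call.cap_site is None else call.cap_site + 1,
                        "three_prime_site_1based": None
                        if call.three_prime_site is None
                        else call.three_prime_site + 1,
                        "polya_len": call.polya_len,
                        "ref_base": ref_base,
                        "category": category,
                        "confidence": call.confidence,
                        "ambiguous_alt_sites_1based": ",".join(
                            str(s + 1) for s in call.ambiguous_alt_sites
                        )
                        or None,
                    }
                )
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)
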