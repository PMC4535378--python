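"""File interchange: FASTA via Biopython, GFF3 and TSV writers/readers.

GFF3 output is 1-based inclusive; the in-memory API is 0-based
half-open, so conversion happens here and only here.
"""

from __future__ import annotations

from typing import Sequence
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ElementCopy, Interval, ReferenceElement, TruthRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _attrs(pairs: dict) -> str:
    return ";".join(f"{k}={quote(str(v), safe='')}" for k, v in pairs.items() if v is not None)


def write_truth_gff3(truths: Sequence[TruthRecord], genome_id: str, path) -> None:
    """Ground-truth insertions as GFF3 (repeat_region + LTR children)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truths:
            attrs = _attrs(
                {
                    "ID": t.copy_id,
                    "family": t.family_name,
                    "age_years": f"{t.insertion_age:g}",
                    "tsd": t.tsd_sequence,
                }
            )
            fh.write(
                "\t".join(
                    [
                        genome_id,
                        "ltrkit_sim",
                        "repeat_region",
                        str(t.genome_interval.start + 1),
                        str(t.genome_interval.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for role, iv in (("five_prime_LTR", t.ltr5_interval), ("three_prime_LTR", t.ltr3_interval)):
                fh.write(
                    "\t".join(
                        [
                            genome_id,
                            "ltrkit_sim",
                            role,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            t.strand,
                            ".",
                            _attrs({"ID": f"{t.copy_id}_{role}", "Parent": t.copy_id}),
                        ]
                    )
                    + "\n"
                )


def read_truth_gff3(path) -> list[TruthRecord]:
    truths: dict[str, dict] = {}
    ltrs: dict[str, dict[str, Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            attrs = {k: unquote(v) for k, v in attrs.items()}
            iv = Interval(int(cols[3]) - 1, int(cols[4]))
            if cols[2] == "repeat_region":
                truths[attrs["ID"]] = {
                    "copy_id": attrs["ID"],
                    "family_name": attrs["family"],
                    "insertion_age": float(attrs["age_years"]),
                    "genome_interval": iv,
                    "tsd_sequence": attrs.get("tsd", ""),
                    "strand": cols[6],
                }
            elif cols[2] in ("five_prime_LTR", "three_prime_LTR"):
                parent = attrs["Parent"]
                ltrs.setdefault(parent, {})[cols[2]] = iv
    out = []
    for cid, kwargs in truths.items():
        kwargs["ltr5_interval"] = ltrs[cid]["five_prime_LTR"]
        kwargs["ltr3_interval"] = ltrs[cid]["three_prime_LTR"]
        out.append(TruthRecord(**kwargs))
    return out


def write_copies_gff3(copies: Sequence[ElementCopy], path) -> None:
    """Mined copies as GFF3 with structural-filter attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            attrs = _attrs(
                {
                    "ID": c.copy_id,
                    "family": c.family_name,
                    "identity": f"{c.identity:.4f}",
                    "coverage": f"{c.coverage:.4f}",
                    "tsd": c.tsd,
                    "termini_ok": str(c.termini_ok).lower(),
                    "status": c.status,
                }
            )
            fh.write(
                "\t".join(
                    [
                        c.genome_id,
                        "ltrkit",
                        "repeat_region",
                        str(c.interval.start + 1),
                        str(c.interval.end),
                        ".",
                        c.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def copies_to_frame(copies: Sequence[ElementCopy]) -> pd.DataFrame:
    rows = []
    for c in copies:
        rows.append(
            {
                "copy_id": c.copy_id,
                "genome_id": c.genome_id,
                "family": c.family_name,
                "start": c.interval.start + 1,
                "end": c.interval.end,
                "strand": c.strand,
                "identity": c.identity,
                "coverage": c.coverage,
                "termini_ok": c.termini_ok,
                "tsd": c.tsd or "",
                "status": c.status,
            }
        )
    return pd.DataFrame(rows)


def read_reference_table(fasta_path, table_path) -> list[ReferenceElement]:
    """Reference panel from a FASTA plus a TSV of LTR annotations.

    The TSV columns are ``id``, ``superfamily``, ``lineage``,
    ``ltr5_start``, ``ltr5_end``, ``ltr3_start``, ``ltr3_end`` with
    1-based inclusive coordinates on the element sequence.
    """
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(table_path, sep="\t")
    refs = []
    for _, row in table.iterrows():
        if row["id"] not in seqs:
            raise ValueError(f"reference {row['id']} missing from FASTA")
        refs.append(
            ReferenceElement(
                family_name=row["id"],
                superfamily=row["superfamily"],
                lineage=row["lineage"],
                sequence=seqs[row["id"]],
                ltr5_interval=Interval(int(row["ltr5_start"]) - 1, int(row["ltr5_end"])),
                ltr3_interval=Interval(int(row["ltr3_start"]) - 1, int(row["ltr3_end"])),
            )
        )
    return refs
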