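"""Core data containers flowing through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_SHEET_COLUMNS = ["sample_id", "site_id", "replicate", "is_negative_control", "marker"]


@dataclass
class ASVTable:
    """ASV x sample read-count matrix plus sample metadata.

    ``counts`` is indexed by ASV id with one column per sample id;
    ``sequences`` maps ASV id to its centroid sequence; ``samples`` is
    indexed by sample id and carries site_id, replicate and the
    negative-control flag.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    samples: pd.DataFrame
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def experimental_columns(self) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if not meta.loc[s, "is_negative_control"]]

    def negative_columns(self) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if meta.loc[s, "is_negative_control"]]

    def drop_empty_asvs(self) -> "ASVTable":
        keep = self.counts.index[(self.counts.sum(axis=1) > 0)]
        return ASVTable(
            counts=self.counts.loc[keep].copy(),
            sequences={a: self.sequences[a] for a in keep},
            samples=self.samples,
            log=dict(self.log),
        )

    # ---- serialisation ----------------------------------------------------
    def write(self, counts_tsv: str | Path, fasta: str | Path) -> None:
        self.counts.to_csv(counts_tsv, sep="\t", index_label="asv_id")
        write_fasta(fasta, [(a, self.sequences[a]) for a in self.counts.index])

    @classmethod
    def read(
        cls, counts_tsv: str | Path, fasta: str | Path, sample_sheet: str | Path
    ) -> "ASVTable":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="asv_id")
        seqs = dict(read_fasta(fasta))
        samples = read_sample_sheet(sample_sheet)
        return cls(counts=counts, sequences=seqs, samples=samples)


# ---- plain-text sequence IO (Biopython-backed) ---------------------------

def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: str | Path, records: list[tuple[str, str, str]]) -> None:
    """Write 4-line FASTQ records given (id, sequence, quality-string)."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"quality length mismatch for {name}")
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        qual = "".join(chr(q + 33) for q in quals)
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    return df.set_index("sample_id")


def write_sample_sheet(path: str | Path, samples: pd.DataFrame) -> None:
    samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(path, index=False)
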