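"""File formats: FASTA sequences, model TSVs, score tables, dataset manifests.

Everything on disk is plain UTF-8 text with LF line endings.  FASTA
records are validated on read against the strict ACGT alphabet; a
sequence containing anything else is a hard error naming the record —
never a silent skip, because a single ambiguous base invalidates every
probability computed from the file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .null_models import IIDModel
from .seqgen import GCMarkDataset
from .sequence import ALPHABET, NucleotideSequence, decode
from .wam import WAMModel


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-FASTA file into validated sequences (uppercased).

    Record order and ids are preserved.  Raises on an empty file or any
    residue outside {A, C, G, T}.
    """
    path = Path(path)
    seqs = [
        NucleotideSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(Path(path)), "fasta-2line")


def write_dataset_fasta(data: GCMarkDataset, path: str | Path) -> None:
    """Write a stratified dataset; headers carry the mark and length."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in range(len(data)):
            fh.write(
                f">{data.ids[i]} mark={int(data.marks[i])} L={data.length}\n"
                f"{decode(data.codes[i])}\n"
            )


def write_dataset_manifest(data: GCMarkDataset, path: str | Path) -> None:
    """Companion TSV: one row per sequence with id, mark and GC count."""
    counts = data.counts()
    pd.DataFrame(
        {
            "id": data.ids,
            "mark": data.marks,
            "gc_count": counts[:, 1] + counts[:, 2],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_iid_model(model: IIDModel, path: str | Path) -> None:
    """Serialize an i.i.d. model as a labelled 4-column TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\t" + "\t".join(ALPHABET) + "\n")
        fh.write(model.label + "\t" + "\t".join(repr(p) for p in model.probs) + "\n")


def read_iid_model(path: str | Path) -> IIDModel:
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] != 1 or list(df.columns) != ["label", *ALPHABET]:
        raise ValueError(f"{path}: not an i.i.d. model TSV")
    row = df.iloc[0]
    return IIDModel(tuple(float(row[b]) for b in ALPHABET), label=str(row["label"]))


def _context_string(index: int, width: int) -> str:
    s = ""
    for _ in range(width):
        s = ALPHABET[index % 4] + s
        index //= 4
    return s


def write_wam(model: WAMModel, path: str | Path) -> None:
    """Serialize a WAM: a ``#``-prefixed header block, then one row per
    (position, context, base) probability."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# length={model.length}\n")
        fh.write(f"# order={model.order}\n")
        fh.write(f"# pseudocount={model.pseudocount!r}\n")
        fh.write("position\tcontext\tbase\tprobability\n")
        for p, d in enumerate(model.dists):
            width = min(p, model.order)
            for ctx in range(d.shape[0]):
                if not model.usable[p][ctx]:
                    continue
                cstr = _context_string(ctx, width) or "-"
                for b in range(4):
                    fh.write(
                        f"{p + 1}\t{cstr}\t{ALPHABET[b]}\t{float(d[ctx, b])!r}\n"
                    )


def read_wam(path: str | Path) -> WAMModel:
    header: dict[str, str] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            elif line and not line.startswith("position\t"):
                rows.append(line.split("\t"))
    try:
        length = int(header["length"])
        order = int(header["order"])
        pseudocount = float(header["pseudocount"])
    except KeyError as e:  # pragma: no cover
        raise ValueError(f"{path}: missing WAM header field {e}") from e

    code = {b: i for i, b in enumerate(ALPHABET)}
    dists = [np.zeros((4 ** min(p, order), 4)) for p in range(length)]
    usable = [np.zeros(4 ** min(p, order), dtype=bool) for p in range(length)]
    for pos_s, ctx_s, base_s, prob_s in rows:
        p = int(pos_s) - 1
        idx = 0
        if ctx_s != "-":
            for ch in ctx_s:
                idx = idx * 4 + code[ch]
        dists[p][idx, code[base_s]] = float(prob_s)
        usable[p][idx] = True
    return WAMModel(dists=dists, order=order, pseudocount=pseudocount, usable=usable)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
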