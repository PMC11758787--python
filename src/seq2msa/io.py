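"""File I/O: FASTA (ungapped and gapped), Newick trees, sentence-pair datasets.

Record order in every format is authoritative and preserved verbatim —
it defines concatenation order for the sentence schemes and permutation
identity for the ensemble.  Gap characters "-" and "–" are both accepted
on input; "-" is always written.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .represent import Sentence, decode_output
from .types import GAP, DatasetRecord, FormatError, Msa, PhyloTree, SequenceSet, infer_alphabet, normalize_gaps

log = logging.getLogger(__name__)


def read_fasta(path: str | Path, gapped: bool = False, alphabet: str | None = None) -> SequenceSet | Msa:
    """Read a FASTA file into a SequenceSet, or an Msa when ``gapped``.

    Gapped mode enforces the alignment invariants (equal row lengths, no
    all-gap column) and raises FormatError on violation.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = [normalize_gaps(str(r.seq).upper()) for r in records]
    if alphabet is None:
        alphabet = infer_alphabet(seqs)
    if gapped:
        return Msa(ids, seqs, alphabet)
    for i, s in enumerate(seqs):
        if GAP in s:
            raise FormatError(f"{path}: gap character in ungapped record {ids[i]!r}")
    return SequenceSet(ids, seqs, alphabet)


def write_fasta(obj: SequenceSet | Msa, path: str | Path) -> None:
    rows = obj.rows if isinstance(obj, Msa) else obj.seqs
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(obj.ids, rows)]
    SeqIO.write(records, str(path), "fasta-2line")


def read_newick(path_or_text: str | Path) -> PhyloTree:
    text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() else str(path_or_text)
    dt = dendropy.Tree.get(data=text, schema="newick")
    parent: list[int] = []
    length: list[float] = []
    labels: list[str | None] = []
    index: dict = {}
    for node in dt.preorder_node_iter():
        index[node] = len(parent)
        parent.append(index[node.parent_node] if node.parent_node else -1)
        length.append(float(node.edge.length or 0.0))
        labels.append(node.taxon.label if node.taxon else None)
    return PhyloTree(parent, length, labels)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_dataset(records: Sequence[DatasetRecord], source_path: str | Path, target_path: str | Path) -> None:
    """Write aligned sentence-pair corpus files, one space-separated sentence per line.

    Line i of the source file corresponds to line i of the target file.
    Every record is checked before writing: decoding its target sentence
    against its ungapped sources must reproduce the truth alignment.
    """
    src_lines, tgt_lines = [], []
    for idx, rec in enumerate(records):
        decoded = decode_output(rec.target, rec.truth.ungapped())
        if not isinstance(decoded, Msa) or decoded.rows != rec.truth.rows:
            raise ValueError(f"record {idx}: target sentence does not decode to its truth alignment")
        src_lines.append(rec.source.text())
        tgt_lines.append(rec.target.text())
    if not records:
        log.warning("writing empty dataset files %s / %s", source_path, target_path)
    Path(source_path).write_text("\n".join(src_lines) + ("\n" if src_lines else ""))
    Path(target_path).write_text("\n".join(tgt_lines) + ("\n" if tgt_lines else ""))


def read_sentences(path: str | Path, scheme: str, k: int) -> list[Sentence]:
    lines = Path(path).read_text().splitlines()
    return [Sentence.from_text(line, scheme, k) for line in lines if line.strip()]


def read_dataset(source_path: str | Path, target_path: str | Path, k: int,
                 input_scheme: str = "concat", output_scheme: str = "spaces") -> list[tuple[Sentence, Sentence]]:
    src = read_sentences(source_path, input_scheme, k)
    tgt = read_sentences(target_path, output_scheme, k)
    if len(src) != len(tgt):
        raise FormatError(f"{len(src)} source lines but {len(tgt)} target lines")
    return list(zip(src, tgt))


def iter_fasta_dir(directory: str | Path, pattern: str = "*.fasta", gapped: bool = False) -> Iterable[tuple[str, SequenceSet | Msa]]:
    for p in sorted(Path(directory).glob(pattern)):
        yield p.stem, read_fasta(p, gapped=gapped)
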