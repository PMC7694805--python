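"""All-vs-all local alignment backend.

Two interchangeable hit sources feed the similarity computation: driving the
external BLAST+ programs (``makeblastdb`` + ``blastn``) with one of four
preset parameter sets, or parsing a precomputed tabular hit file.  Both yield
the same canonical :class:`AlignmentHit` records.

Coordinate conventions: the tabular dialect is 1-based inclusive with
minus-strand subject hits encoded by ``s.start > s.end``; internally all
intervals are 0-based half-open with the strand carried separately.  The
conversion lives entirely in :func:`normalize_hit`.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from igsim.errors import AlignerError, AlignerNotFoundError, HitTableError
from igsim.genome_io import GenomeSet, write_fasta

#: Tabular output: the standard 12 columns plus the identical-match count.
OUTFMT_FIELDS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore nident"
)


@dataclass(frozen=True)
class BlastParameterSet:
    """One of the four blastn parameter presets (set 1 is the default)."""

    set_id: int
    word_size: int
    reward: int
    penalty: int
    gapopen: int | None = None
    gapextend: int | None = None

    def to_args(self) -> list[str]:
        args = [
            "-word_size", str(self.word_size),
            "-reward", str(self.reward),
            "-penalty", str(self.penalty),
        ]
        if self.gapopen is not None:
            args += ["-gapopen", str(self.gapopen)]
        if self.gapextend is not None:
            args += ["-gapextend", str(self.gapextend)]
        return args


#: Preset ladder from "relaxed" (1, default) to "very stringent" (4).
PARAMETER_SETS: dict[int, BlastParameterSet] = {
    1: BlastParameterSet(1, word_size=7, reward=2, penalty=-3, gapopen=5, gapextend=2),
    2: BlastParameterSet(2, word_size=11, reward=2, penalty=-3, gapopen=5, gapextend=2),
    3: BlastParameterSet(3, word_size=20, reward=1, penalty=-2),
    4: BlastParameterSet(4, word_size=28, reward=1, penalty=-2),
}

DEFAULT_PARAMETER_SET = PARAMETER_SETS[1]


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment hit (HSP) between two genomes.

    Intervals are 0-based half-open; ``s_strand`` is '-' when the raw subject
    coordinates were descending.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    s_strand: str
    align_len: int
    n_ident: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start}, {self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval [{self.s_start}, {self.s_end})")
        if self.s_strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.s_strand!r}")
        if self.n_ident > self.align_len:
            raise ValueError("n_ident exceeds alignment length")
        if self.n_ident > self.q_end - self.q_start:
            raise ValueError("n_ident exceeds query interval length")
        if self.n_ident > self.s_end - self.s_start:
            raise ValueError("n_ident exceeds subject interval length")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def normalize_hit(
    query_id: str,
    subject_id: str,
    q_start: int,
    q_end: int,
    s_start: int,
    s_end: int,
    align_len: int,
    n_ident: int,
    bitscore: float = 0.0,
    evalue: float = 0.0,
) -> AlignmentHit:
    """Convert raw 1-based inclusive coordinates to a canonical hit.

    Minus-strand subject hits (``s_start > s_end`` in the raw row) are flipped
    so the stored interval is ascending and the strand is '-'.
    """
    if q_start > q_end:
        raise ValueError("query coordinates must be ascending in the tabular dialect")
    strand = "+"
    if s_start > s_end:
        s_start, s_end = s_end, s_start
        strand = "-"
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        q_start=q_start - 1,
        q_end=q_end,
        s_start=s_start - 1,
        s_end=s_end,
        s_strand=strand,
        align_len=align_len,
        n_ident=n_ident,
        bitscore=bitscore,
        evalue=evalue,
    )


def parse_hit_table(
    path: str | Path, genome_set: GenomeSet | None = None
) -> list[AlignmentHit]:
    """Parse a 13-column tabular hit file into normalized hits.

    Expected columns: query id, subject id, % identity, alignment length,
    mismatches, gap opens, q.start, q.end, s.start, s.end, evalue, bitscore,
    identical matches.  Self-hit rows (query id == subject id) are dropped.
    When ``genome_set`` is given, unknown ids are an error.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                raise HitTableError(
                    f"{path}:{lineno}: expected >= 13 tab-separated columns, "
                    f"got {len(cols)}"
                )
            qid, sid = cols[0], cols[1]
            if qid == sid:
                continue
            if genome_set is not None:
                for gid in (qid, sid):
                    if gid not in genome_set:
                        raise HitTableError(
                            f"{path}:{lineno}: unknown genome id {gid!r}"
                        )
            try:
                hit = normalize_hit(
                    query_id=qid,
                    subject_id=sid,
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    align_len=int(cols[3]),
                    n_ident=int(cols[12]),
                    bitscore=float(cols[11]),
                    evalue=float(cols[10]),
                )
            except (ValueError, IndexError) as exc:
                raise HitTableError(f"{path}:{lineno}: malformed row ({exc})") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> Path:
    """Write hits back to the 13-column tabular dialect (inverse of parsing)."""
    path = Path(path)
    with open(path, "w") as out:
        for h in hits:
            if h.s_strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            pident = 100.0 * h.n_ident / h.align_len
            mism = h.align_len - h.n_ident
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, f"{pident:.3f}", h.align_len,
                        mism, 0, h.q_start + 1, h.q_end, ss, se,
                        f"{h.evalue:g}", f"{h.bitscore:g}", h.n_ident,
                    )
                )
                + "\n"
            )
    return path


def _require(binary: str) -> str:
    found = shutil.which(binary)
    if found is None:
        raise AlignerNotFoundError(
            f"required aligner binary {binary!r} not found on PATH"
        )
    return found


def _run(cmd: Sequence[str], log: list[str] | None) -> subprocess.CompletedProcess:
    if log is not None:
        log.append(" ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise AlignerError(
            f"command failed with exit code {proc.returncode}: {' '.join(cmd)}\n"
            f"{proc.stderr.strip()}"
        )
    return proc


def aligner_version() -> str:
    proc = _run([_require("blastn"), "-version"], None)
    return proc.stdout.splitlines()[0].strip()


def run_all_vs_all(
    gs: GenomeSet,
    params: BlastParameterSet = DEFAULT_PARAMETER_SET,
    evalue: float = 1.0,
    max_targets: int = 10000,
    threads: int = 1,
    work_dir: str | Path | None = None,
    command_log: list[str] | None = None,
) -> list[AlignmentHit]:
    """Align every genome against every other genome with blastn.

    Builds a nucleotide database over the whole set and queries it with the
    same set, so hits for both directions of every pair are produced in one
    invocation.  Self-hits are dropped.  Exact command lines are appended to
    ``command_log`` when provided.
    """
    if len(gs) < 2:
        raise ValueError("need at least 2 genomes for all-vs-all alignment")
    makeblastdb = _require("makeblastdb")
    blastn = _require("blastn")

    def _align(tmp: Path) -> list[AlignmentHit]:
        fasta = write_fasta(gs, tmp / "genomes.fasta")
        db = tmp / "genomes_db"
        _run(
            [makeblastdb, "-in", str(fasta), "-dbtype", "nucl", "-out", str(db)],
            command_log,
        )
        out_tsv = tmp / "hits.tsv"
        cmd = [
            blastn,
            "-query", str(fasta),
            "-db", str(db),
            "-evalue", str(evalue),
            "-max_target_seqs", str(max_targets),
            "-num_threads", str(threads),
            *params.to_args(),
            "-outfmt", f"6 {OUTFMT_FIELDS}",
            "-out", str(out_tsv),
        ]
        _run(cmd, command_log)
        return parse_hit_table(out_tsv, genome_set=gs)

    if work_dir is not None:
        work_dir = Path(work_dir)
        work_dir.mkdir(parents=True, exist_ok=True)
        return _align(work_dir)
    with tempfile.TemporaryDirectory(prefix="igsim_blast_") as tmp:
        return _align(Path(tmp))
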