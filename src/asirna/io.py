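"""File readers/writers and the candidate design report.

All tabular outputs are TSV with ``#``-prefixed metadata header lines (tool
version, seed, input fingerprints) sufficient to reproduce the run; no
timestamps, so reruns with identical inputs are byte-identical.  FASTA input is
read with Biopython and may be gzip-compressed.
"""

from __future__ import annotations

import gzip
import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .matrix import MismatchMatrix, discrimination, predict_eff_wild
from .model import EfficacyModel, predict_eff_mut
from .offtarget import build_seed_index, seed_offtargets
from .sequence import AllelePair, SiRNACandidate, parse_allele_pair

__all__ = [
    "read_fasta",
    "read_allele_fasta",
    "file_fingerprint",
    "metadata_header",
    "write_tsv",
    "candidates_frame",
    "design_report",
    "hits_frame",
    "write_bed",
]

REPORT_SCHEMA_VERSION = 1


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {id: sequence} mapping."""
    with _open_maybe_gzip(path) as fh:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_allele_fasta(
    mutant_path: str | Path, wild_path: str | Path | None = None
) -> AllelePair:
    """Read the mutant/wild allele pair from one two-record FASTA or two files.

    The variant is marked by a single lowercase nucleotide in each record
    (case is preserved by the reader and interpreted by the parser).
    """
    with _open_maybe_gzip(mutant_path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if wild_path is None:
        if len(records) != 2:
            raise ValueError(
                f"{mutant_path}: expected 2 records (mutant then wild), "
                f"found {len(records)}"
            )
        mutant_raw, wild_raw = str(records[0].seq), str(records[1].seq)
    else:
        if len(records) != 1:
            raise ValueError(f"{mutant_path}: expected a single mutant record")
        mutant_raw = str(records[0].seq)
        with _open_maybe_gzip(wild_path) as fh:
            wild_records = list(SeqIO.parse(fh, "fasta"))
        if len(wild_records) != 1:
            raise ValueError(f"{wild_path}: expected a single wild-type record")
        wild_raw = str(wild_records[0].seq)
    return parse_allele_pair(mutant_raw, wild_raw)


def file_fingerprint(path: str | Path) -> str:
    """Short SHA-256 of a file's bytes, for reproducibility headers."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def metadata_header(**fields: object) -> list[str]:
    """Standard metadata lines: tool version, schema version, then caller fields."""
    lines = [
        f"asirna_version={__version__}",
        f"schema_version={REPORT_SCHEMA_VERSION}",
    ]
    lines += [f"{k}={v}" for k, v in fields.items() if v is not None]
    return lines


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def candidates_frame(candidates: Sequence[SiRNACandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "guide": [c.guide for c in candidates],
            "variant_guide_pos": [c.variant_guide_pos for c in candidates],
            "target_window_start": [c.target_window_start for c in candidates],
            "target_window": [c.target_window for c in candidates],
        }
    )


def design_report(
    pair: AllelePair,
    candidates: Sequence[SiRNACandidate],
    model: EfficacyModel,
    matrix: MismatchMatrix,
    offtarget_db: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-candidate design table: Eff_mut, Eff_wild, discrimination, seed hits.

    One row per candidate ordered by variant guide position; when no off-target
    database is supplied the seed off-target columns are left empty.
    """
    eff_mut = predict_eff_mut(model, candidates)
    rows = []
    idx6 = idx7 = None
    if offtarget_db is not None:
        idx6 = build_seed_index(offtarget_db, 6)
        idx7 = build_seed_index(offtarget_db, 7)
    for cand, em in zip(candidates, eff_mut):
        ew = predict_eff_wild(float(em), cand, pair, matrix)
        row = {
            "guide": cand.guide,
            "variant_guide_pos": cand.variant_guide_pos,
            "target_window_start": cand.target_window_start,
            "eff_mut": float(em),
            "eff_wild": ew,
            "discrimination": discrimination(float(em), ew),
            "offtargets_seed6": np.nan,
            "offtargets_seed7": np.nan,
        }
        if offtarget_db is not None:
            row["offtargets_seed6"] = len(seed_offtargets(cand.guide, idx6, "seed6"))
            row["offtargets_seed7"] = len(seed_offtargets(cand.guide, idx7, "seed7"))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("variant_guide_pos", ignore_index=True)


def hits_frame(hits, guide_id: str = "guide") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "guide_id": [guide_id] * len(hits),
            "sequence_id": [h.sequence_id for h in hits],
            "start": [h.start for h in hits],
            "mode": [h.mode for h in hits],
            "mismatches": [h.mismatches for h in hits],
            "site": [h.site for h in hits],
        }
    )


def write_bed(hits, path: str | Path, guide_id: str = "guide") -> None:
    """Write hits as BED (0-based half-open conversion handled here)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start - 1}\t{h.start - 1 + len(h.site)}"
                f"\t{guide_id}:{h.mode}\t{h.mismatches}\t+\n"
            )
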