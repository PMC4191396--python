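"""Readers/writers for the pipeline's TSV artifacts and FASTA counting.

All tables are UTF-8 TSV with a header row and '.' decimal separator.
Round trips are lossless to float precision; malformed rows are rejected
with the offending line number.  A header-only file reads back as an empty
table, not an error.

The genomic part counts overlapping di-/tri-/tetranucleotide windows
containing the CG step, pools each k-mer with its reverse complement
(self-complementary k-mers are not double-counted) and normalizes by the
number of counted windows.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .helimap import HelicalAxisFrames
from .thermo import UmbrellaWindow

__all__ = [
    "read_snapshot_series", "write_snapshot_series",
    "read_ion_records", "write_ion_records",
    "read_axis_frames", "write_axis_frames",
    "write_density_grid",
    "read_umbrella_windows", "write_umbrella_windows",
    "count_cg_oligos", "apply_burn_in",
]

SNAPSHOT_COLUMNS = ["snapshot", "time_ps", "twist_deg", "zetaW_deg",
                    "zetaC_deg", "mgw_A", "slide_A", "contact"]
ION_COLUMNS = ["snapshot", "ion_id", "species", "D", "R_A", "A_deg"]
AXIS_COLUMNS = ["level", "ox", "oy", "oz", "tx", "ty", "tz", "rx", "ry", "rz"]


class TableFormatError(ValueError):
    """A TSV artifact violated the expected dialect or schema."""


def _read_tsv(path_or_buf, required, numeric):
    try:
        df = pd.read_csv(path_or_buf, sep="\t")
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path_or_buf}: file has no header row") from None
    except pd.errors.ParserError as e:
        raise TableFormatError(f"{path_or_buf}: {e}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path_or_buf}: missing columns {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
            raise TableFormatError(
                f"{path_or_buf}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced
    return df


def write_snapshot_series(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SNAPSHOT_COLUMNS)


def read_snapshot_series(path) -> pd.DataFrame:
    df = _read_tsv(path, SNAPSHOT_COLUMNS, [c for c in SNAPSHOT_COLUMNS if c != "contact"])
    df["snapshot"] = df["snapshot"].astype(int)
    df["contact"] = df["contact"].astype(int)
    return df[SNAPSHOT_COLUMNS]


def write_ion_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ION_COLUMNS)


def read_ion_records(path) -> pd.DataFrame:
    df = _read_tsv(path, ION_COLUMNS, ["snapshot", "ion_id", "D", "R_A", "A_deg"])
    df["snapshot"] = df["snapshot"].astype(int)
    df["ion_id"] = df["ion_id"].astype(int)
    return df[ION_COLUMNS]


def write_axis_frames(axis: HelicalAxisFrames, path) -> None:
    df = pd.DataFrame(
        np.column_stack([axis.levels, axis.origins, axis.tangents, axis.references]),
        columns=AXIS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_axis_frames(path) -> HelicalAxisFrames:
    df = _read_tsv(path, AXIS_COLUMNS, AXIS_COLUMNS)
    return HelicalAxisFrames(
        levels=df["level"].to_numpy(),
        origins=df[["ox", "oy", "oz"]].to_numpy(),
        tangents=df[["tx", "ty", "tz"]].to_numpy(),
        references=df[["rx", "ry", "rz"]].to_numpy(),
    )


def write_density_grid(grid, path) -> None:
    """Long-format TSV: one row per bin with edges, mean count and molarity."""
    rows = []
    coords = grid.coords
    if len(coords) == 1:
        e = grid.edges[coords]
        for i in range(len(e) - 1):
            rows.append((e[i], e[i + 1], np.nan, np.nan,
                         grid.mean_count[i], grid.molarity[i]))
        cols = [f"{coords}_lo", f"{coords}_hi", "unused_lo", "unused_hi",
                "mean_count", "molarity_M"]
    else:
        c1, c2 = coords
        e1, e2 = grid.edges[c1], grid.edges[c2]
        for i in range(len(e1) - 1):
            for j in range(len(e2) - 1):
                rows.append((e1[i], e1[i + 1], e2[j], e2[j + 1],
                             grid.mean_count[i, j], grid.molarity[i, j]))
        cols = [f"{c1}_lo", f"{c1}_hi", f"{c2}_lo", f"{c2}_hi",
                "mean_count", "molarity_M"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_umbrella_windows(windows, directory, manifest_name="windows.tsv") -> Path:
    """One two-column TSV per window plus a manifest (file, center, k)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.tsv"
        pd.DataFrame({"sample": np.arange(w.samples.size), "zeta_deg": w.samples}) \
            .to_csv(directory / fname, sep="\t", index=False)
        rows.append((fname, w.center, w.k))
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=["file", "center_deg", "k_kcal_deg2"]) \
        .to_csv(manifest, sep="\t", index=False)
    return manifest


def read_umbrella_windows(manifest_path):
    manifest_path = Path(manifest_path)
    man = _read_tsv(manifest_path, ["file", "center_deg", "k_kcal_deg2"],
                    ["center_deg", "k_kcal_deg2"])
    windows = []
    for _, row in man.iterrows():
        wdf = _read_tsv(manifest_path.parent / row["file"], ["zeta_deg"], ["zeta_deg"])
        windows.append(UmbrellaWindow(center=float(row["center_deg"]),
                                      k=float(row["k_kcal_deg2"]),
                                      samples=wdf["zeta_deg"].to_numpy()))
    return windows


def apply_burn_in(n_total: int, burn_in) -> int:
    """First snapshot index kept after burn-in.

    ``burn_in`` is a fraction in [0, 1) (discard that share of the series,
    mirroring the last-200-of-500-ns analysis convention) or an explicit
    snapshot count (int >= 1).
    """
    if isinstance(burn_in, float) and 0 <= burn_in < 1:
        return int(round(n_total * burn_in))
    if isinstance(burn_in, (int, np.integer)) and 0 <= burn_in <= n_total:
        return int(burn_in)
    raise ValueError(f"burn_in must be a fraction in [0,1) or a count, got {burn_in!r}")


# ---------------------------------------------------------------------------
# FASTA oligonucleotide frequency
# ---------------------------------------------------------------------------

_VALID = set("ACGTN")


def _iter_sequences(source):
    """Yield (record_id, sequence) from FASTA path/handle/text, explicit
    sequence lists or Biopython records."""
    if isinstance(source, (str, Path)):
        text = str(source)
        if "\n" in text or text.lstrip().startswith(">"):
            handle = _io.StringIO(text)
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq).upper()
            return
        for rec in SeqIO.parse(source, "fasta"):
            yield rec.id, str(rec.seq).upper()
        return
    if hasattr(source, "read"):
        for rec in SeqIO.parse(source, "fasta"):
            yield rec.id, str(rec.seq).upper()
        return
    for i, item in enumerate(source, start=1):
        if hasattr(item, "seq"):
            yield getattr(item, "id", f"seq{i}"), str(item.seq).upper()
        elif isinstance(item, str) and item.lstrip().startswith(">"):
            for rec in SeqIO.parse(_io.StringIO(item), "fasta"):
                yield rec.id, str(rec.seq).upper()
        else:
            yield f"seq{i}", str(item).upper()


def count_cg_oligos(source, k: int) -> pd.DataFrame:
    """Frequencies of CG-containing k-mers, pooled with reverse complements.

    Counts every overlapping window of width ``k`` (step 1) whose forward
    string contains the substring "CG"; windows containing N are skipped
    (and excluded from the normalization).  Each k-mer is pooled with its
    reverse complement under the lexicographically smaller key; a
    self-complementary k-mer (e.g. TCGA) is pooled with itself exactly
    once.  Returns a DataFrame indexed by the canonical k-mer with columns
    ``count_fwd`` (raw forward count of the canonical k-mer),
    ``count_revcomp`` (raw count of its partner), ``pooled_count`` and
    ``frequency`` (pooled count / total counted windows).

    Raises ``ValueError`` naming the record and offset for characters
    outside {A, C, G, T, N}.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    raw: dict = {}
    total_windows = 0
    for rec_id, seq in _iter_sequences(source):
        bad = set(seq) - _VALID
        if bad:
            offset = next(i for i, ch in enumerate(seq) if ch in bad)
            raise ValueError(
                f"record {rec_id!r}: invalid character {seq[offset]!r} at offset {offset}"
            )
        for i in range(len(seq) - k + 1):
            w = seq[i: i + k]
            if "N" in w:
                continue
            total_windows += 1
            if "CG" in w:
                raw[w] = raw.get(w, 0) + 1
    rows = {}
    for kmer, count in raw.items():
        rc = str(Seq(kmer).reverse_complement())
        canon = min(kmer, rc)
        if canon not in rows:
            rc_canon = str(Seq(canon).reverse_complement())
            fwd = raw.get(canon, 0)
            rev = raw.get(rc_canon, 0)
            pooled = fwd if canon == rc_canon else fwd + rev
            rows[canon] = (rc_canon, fwd, rev, pooled)
    df = pd.DataFrame(
        [(k_, v[0], v[1], v[2], v[3]) for k_, v in sorted(rows.items())],
        columns=["kmer", "revcomp", "count_fwd", "count_revcomp", "pooled_count"],
    ).set_index("kmer")
    df["frequency"] = (
        df["pooled_count"] / total_windows if total_windows else np.nan
    )
    return df
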