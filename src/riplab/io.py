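"""Readers and writers for the tabular, FASTA and BED formats used by all stages.

Every writer's output round-trips through the corresponding reader.
Malformed rows are rejected with the offending column and line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .behavior_stats import CourtshipObservation
from .cpe_scan import CpeCensus, MotifHit, MotifSet
from .errors import InputError
from .quant import DilutionSeries
from .rip_enrichment import SAMPLE_COLUMNS

__all__ = [
    "read_bouts",
    "read_counts",
    "read_ct",
    "read_densitometry",
    "read_fasta",
    "read_gene_set",
    "read_gmt",
    "read_motifs_yaml",
    "write_bed6",
    "write_bouts",
    "write_census",
    "write_counts",
    "write_densitometry",
    "write_enrichment",
    "write_fasta",
    "write_gene_list",
]

_COUNT_COLUMNS = ("gene_id", "biotype", "input", "ip", "mock_ip")
_BOUT_COLUMNS = ("male_id", "group", "bout_start_s", "bout_end_s", "observation_s")
_DENS_COLUMNS = (
    "genotype",
    "fraction",
    "replicate",
    "lane",
    "relative_load",
    "chemi_signal",
    "total_protein_signal",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count TSV (gene_id, biotype, input, ip, mock_ip) -> validated DataFrame."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _COUNT_COLUMNS, path)
    for col in SAMPLE_COLUMNS:
        bad = df.index[(df[col] < 0) | df[col].isna() | (df[col] % 1 != 0)]
        if len(bad):
            line = int(bad[0]) + 2  # header is line 1
            raise InputError(
                f"{path}: column {col!r}, line {line}: counts must be "
                "non-negative integers"
            )
    dup = df["gene_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise InputError(f"{path}: column 'gene_id', line {line}: duplicate gene id")
    out = df.set_index("gene_id")
    out[list(SAMPLE_COLUMNS)] = out[list(SAMPLE_COLUMNS)].astype(int)
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.reset_index(names="gene_id").to_csv(path, sep="\t", index=False)


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index(names="gene_id").to_csv(path, sep="\t", index=False)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: tab-separated `name<TAB>description<TAB>gene...` per line."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}: line {i}: GMT rows need name, description, genes")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: sequence} (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    """FASTA wrapped at 80 columns."""
    recs = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_bouts(path: str | Path) -> list[CourtshipObservation]:
    """Bout-log CSV -> observations, one per male.

    Rows with empty bout_start_s/bout_end_s declare a male with no bouts.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _BOUT_COLUMNS, path)
    bad = df.index[df["bout_start_s"].notna() & (df["bout_end_s"] <= df["bout_start_s"])]
    if len(bad):
        line = int(bad[0]) + 2
        raise InputError(
            f"{path}: column 'bout_end_s', line {line}: bout end must exceed start"
        )
    observations = []
    for (male, group, obs_s), rows in df.groupby(
        ["male_id", "group", "observation_s"], sort=False
    ):
        bouts = [
            (float(r.bout_start_s), float(r.bout_end_s))
            for r in rows.itertuples()
            if pd.notna(r.bout_start_s)
        ]
        observations.append(
            CourtshipObservation(
                male_id=str(male), group=str(group), bouts=bouts,
                observation_s=float(obs_s),
            )
        )
    return observations


def write_bouts(observations: Sequence[CourtshipObservation], path: str | Path) -> None:
    rows = []
    for obs in observations:
        if not obs.bouts:
            rows.append((obs.male_id, obs.group, None, None, obs.observation_s))
        for start, end in obs.bouts:
            rows.append((obs.male_id, obs.group, start, end, obs.observation_s))
    pd.DataFrame(rows, columns=_BOUT_COLUMNS).to_csv(path, index=False)


def read_densitometry(path: str | Path) -> list[DilutionSeries]:
    """Densitometry CSV -> one DilutionSeries per (genotype, fraction, replicate)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _DENS_COLUMNS, path)
    bad = df.index[(df["relative_load"] <= 0) | df["relative_load"].isna()]
    if len(bad):
        line = int(bad[0]) + 2
        raise InputError(
            f"{path}: column 'relative_load', line {line}: loads must be positive"
        )
    series = []
    for (genotype, fraction, rep), rows in df.groupby(
        ["genotype", "fraction", "replicate"], sort=False
    ):
        series.append(
            DilutionSeries(
                genotype=str(genotype),
                fraction=str(fraction),
                replicate=str(rep),
                lanes=tuple(
                    (float(r.relative_load), float(r.chemi_signal),
                     float(r.total_protein_signal))
                    for r in rows.itertuples()
                ),
            )
        )
    return series


def write_densitometry(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ct(path: str | Path) -> pd.DataFrame:
    """Ct CSV with columns sample, ct_target, ct_reference (extras kept)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("sample", "ct_target", "ct_reference"), path)
    for col in ("ct_target", "ct_reference"):
        bad = df.index[df[col].isna() | (df[col] <= 0)]
        if len(bad):
            line = int(bad[0]) + 2
            raise InputError(
                f"{path}: column {col!r}, line {line}: Ct must be finite and positive"
            )
    return df


def read_motifs_yaml(path: str | Path) -> MotifSet:
    """YAML with `canonical:` and `noncanonical:` pattern lists."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not {"canonical", "noncanonical"} <= set(data):
        raise InputError(f"{path}: motif YAML needs 'canonical' and 'noncanonical' lists")
    return MotifSet(
        canonical=tuple(data["canonical"]),
        noncanonical=tuple(data["noncanonical"]),
    )


def write_bed6(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Motif hits as BED6: seq id, start, end, pattern, score 0, '+' strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.pattern}\t0\t+\n")


def write_census(censuses: Sequence[CpeCensus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "n_canonical": c.n_canonical,
                "n_noncanonical": c.n_noncanonical,
                "n_total": c.n_total,
            }
            for c in censuses
        ]
    ).to_csv(path, sep="\t", index=False)
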