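"""Reading, harmonizing and filtering GWAS summary statistics (the "munge" step).

Per trait, SNPs are dropped when the minor-allele frequency is below 1%,
the imputation INFO score is below 0.9, the SNP lies in the MHC region, or
the allele pair is strand-ambiguous (A/T, C/G). Alleles are then aligned
across traits to the first trait's A1/A2 orientation, flipping z signs on
swapped alleles and dropping mismatches, and all traits are restricted to
the common surviving SNP set. Filter order is fixed: duplicate -> MAF ->
INFO -> MHC -> ambiguous -> cross-trait alignment/intersection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .simulate import SummaryStats

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCReport", "read_sumstats", "munge"]

_RULES = ("duplicate", "malformed", "maf", "info", "mhc", "ambiguous", "unmatched")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: case-insensitive synonyms accepted for each canonical column
_SYNONYMS = {
    "SNP": ("snp", "rsid", "markername", "snpid", "rs_number"),
    "CHR": ("chr", "chrom", "chromosome"),
    "BP": ("bp", "pos", "position", "base_pair"),
    "A1": ("a1", "allele1", "effect_allele", "ea"),
    "A2": ("a2", "allele2", "other_allele", "oa", "non_effect_allele"),
    "Z": ("z", "zscore", "z_score", "stat"),
    "BETA": ("beta", "b", "effect"),
    "SE": ("se", "stderr", "standard_error"),
    "N": ("n", "nobs", "samplesize", "n_total"),
    "INFO": ("info", "imputation_quality"),
    "FRQ": ("frq", "freq", "maf", "eaf", "af", "frq_a1"),
}


@dataclass(frozen=True)
class QCThresholds:
    """Munge filter settings.

    Defaults follow the published filter: MAF < 1%, INFO < 0.9 and the MHC
    region removed. The MHC interval defaults to the GRCh37 convention,
    chromosome 6, 26-34 Mb (1-based, closed); the region is named without
    coordinates in most reports, so it is configurable.
    """

    maf_min: float = 0.01
    info_min: float = 0.9
    mhc_interval: tuple[str, int, int] = ("6", 26_000_000, 34_000_000)
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ConfigurationError("maf_min must be in [0, 0.5)")
        if not (0.0 <= self.info_min <= 1.0):
            raise ConfigurationError("info_min must be in [0, 1]")
        chrom, lo, hi = self.mhc_interval
        if lo > hi:
            raise ConfigurationError("MHC interval start must be <= end")


@dataclass
class QCReport:
    """Counts of SNPs dropped per rule and per trait, plus retained count."""

    per_trait: dict = field(default_factory=dict)
    retained: int = 0

    def add(self, trait: str, rule: str, count: int) -> None:
        self.per_trait.setdefault(trait, {r: 0 for r in _RULES})
        self.per_trait[trait][rule] += int(count)

    def input_count(self, trait: str) -> int:
        return sum(self.per_trait.get(trait, {}).values()) + self.retained

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"per_trait": self.per_trait,
                              "retained": self.retained}, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def __str__(self) -> str:
        lines = []
        for trait, counts in self.per_trait.items():
            dropped = ", ".join(f"{r}={c}" for r, c in counts.items() if c)
            lines.append(f"{trait}: dropped [{dropped or 'none'}]")
        lines.append(f"retained (common SNP set): {self.retained}")
        return "\n".join(lines)


def _resolve_columns(columns, dialect: dict | None) -> dict[str, str]:
    """Map canonical names to actual file columns (dialect wins, then synonyms)."""
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    dialect = dialect or {}
    for canon, syns in _SYNONYMS.items():
        if canon in dialect:
            if dialect[canon] not in columns:
                raise ConfigurationError(
                    f"dialect maps {canon!r} to missing column {dialect[canon]!r}")
            resolved[canon] = dialect[canon]
            continue
        for s in (canon.lower(),) + syns:
            if s in lower:
                resolved[canon] = lower[s]
                break
    return resolved


def read_sumstats(path: str | Path, dialect: dict | None = None,
                  trait: str | None = None, sep: str = "\t") -> SummaryStats:
    """Read one trait's summary statistics from delimited text.

    Accepts a Z column, or BETA+SE converted as z = beta/se. Malformed
    numeric rows are dropped and reported with their line numbers;
    duplicated SNP ids keep the first occurrence. Both counts land in
    ``qc_notes`` and are folded into the munge QC report.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"sumstats file not found: {path}")
    raw = pd.read_csv(path, sep=sep, dtype=str)
    cols = _resolve_columns(raw.columns, dialect)
    if "SNP" not in cols:
        raise ConfigurationError(f"{path}: no SNP id column resolvable")
    if "Z" not in cols and not ("BETA" in cols and "SE" in cols):
        raise ConfigurationError(f"{path}: need a Z column or BETA+SE")
    if "N" not in cols:
        raise ConfigurationError(f"{path}: no sample-size (N) column resolvable")

    tab = pd.DataFrame({"SNP": raw[cols["SNP"]].astype(str)})
    tab["CHR"] = raw[cols["CHR"]].astype(str) if "CHR" in cols else "0"
    tab["BP"] = (pd.to_numeric(raw[cols["BP"]], errors="coerce")
                 if "BP" in cols else np.arange(1, len(raw) + 1))
    for canon in ("A1", "A2"):
        if canon in cols:
            tab[canon] = raw[cols[canon]].str.upper()
    if "Z" in cols:
        tab["Z"] = pd.to_numeric(raw[cols["Z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[cols["BETA"]], errors="coerce")
        se = pd.to_numeric(raw[cols["SE"]], errors="coerce")
        tab["Z"] = beta / se
    tab["N"] = pd.to_numeric(raw[cols["N"]], errors="coerce")
    for canon in ("INFO", "FRQ"):
        if canon in cols:
            tab[canon] = pd.to_numeric(raw[cols[canon]], errors="coerce")

    notes: dict = {}
    bad = tab["Z"].isna() | tab["N"].isna() | pd.isna(tab["BP"])
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header, 1-based
        notes["malformed"] = int(bad.sum())
        notes["malformed_lines"] = lines[:20]
        logger.warning("%s: dropped %d malformed rows (lines %s%s)", path,
                       bad.sum(), lines[:20], "..." if len(lines) > 20 else "")
        tab = tab[~bad]
    dup = tab["SNP"].duplicated()
    if dup.any():
        notes["duplicate"] = int(dup.sum())
        logger.warning("%s: dropped %d duplicate SNP ids (kept first)", path, dup.sum())
        tab = tab[~dup]
    tab = tab.reset_index(drop=True)
    tab["BP"] = tab["BP"].astype(np.int64)
    return SummaryStats(trait=trait or path.stem, table=tab, qc_notes=notes)


def _is_ambiguous(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def munge(stats: list[SummaryStats], thresholds: QCThresholds | None = None
          ) -> tuple[list[SummaryStats], QCReport]:
    """Filter and harmonize all traits; returns munged stats and a QC report.

    Missing INFO/FRQ columns skip the corresponding filter with a logged
    warning. The first trait defines the A1/A2 orientation; swapped alleles
    in later traits flip the z sign (and FRQ), mismatched allele pairs are
    dropped, and every trait is restricted to the common surviving SNP set,
    sorted by genomic position.
    """
    if not stats:
        raise ConfigurationError("no summary statistics supplied")
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    filtered: list[pd.DataFrame] = []
    for st in stats:
        tab = st.table.copy()
        for rule in ("malformed", "duplicate"):
            report.add(st.trait, rule, st.qc_notes.get(rule, 0))
        dup = tab["SNP"].duplicated()
        if dup.any():
            report.add(st.trait, "duplicate", int(dup.sum()))
            tab = tab[~dup]
        if "FRQ" in tab:
            frq = tab["FRQ"].to_numpy(dtype=float)
            keep = np.minimum(frq, 1.0 - frq) >= thresholds.maf_min
            report.add(st.trait, "maf", int((~keep).sum()))
            tab = tab[keep]
        else:
            logger.warning("%s: no FRQ column, MAF filter skipped", st.trait)
        if "INFO" in tab:
            keep = tab["INFO"].to_numpy(dtype=float) >= thresholds.info_min
            report.add(st.trait, "info", int((~keep).sum()))
            tab = tab[keep]
        else:
            logger.warning("%s: no INFO column, INFO filter skipped", st.trait)
        chrom, lo, hi = thresholds.mhc_interval
        in_mhc = ((tab["CHR"].astype(str) == str(chrom))
                  & (tab["BP"] >= lo) & (tab["BP"] <= hi))
        report.add(st.trait, "mhc", int(in_mhc.sum()))
        tab = tab[~in_mhc]
        if thresholds.drop_ambiguous and "A1" in tab and "A2" in tab:
            amb = _is_ambiguous(tab["A1"], tab["A2"])
            report.add(st.trait, "ambiguous", int(amb.sum()))
            tab = tab[~amb]
        filtered.append(tab.reset_index(drop=True))

    # align alleles across traits to trait 1's orientation
    ref = filtered[0].set_index("SNP")
    aligned = [filtered[0]]
    for st, tab in zip(stats[1:], filtered[1:]):
        tab = tab[tab["SNP"].isin(ref.index)]
        ra1 = tab["SNP"].map(ref["A1"])
        ra2 = tab["SNP"].map(ref["A2"])
        if "A1" in tab and "A2" in tab:
            same = (tab["A1"] == ra1) & (tab["A2"] == ra2)
            swapped = (tab["A1"] == ra2) & (tab["A2"] == ra1)
            n_bad = int((~(same | swapped)).sum())
            report.add(st.trait, "unmatched", n_bad)
            tab = tab[same | swapped].copy()
            flip = swapped[same | swapped]
            tab.loc[flip, "Z"] = -tab.loc[flip, "Z"]
            if "FRQ" in tab:
                tab.loc[flip, "FRQ"] = 1.0 - tab.loc[flip, "FRQ"]
            tab.loc[flip, ["A1", "A2"]] = tab.loc[flip, ["A2", "A1"]].to_numpy()
        aligned.append(tab.reset_index(drop=True))

    common = set(aligned[0]["SNP"])
    for tab in aligned[1:]:
        common &= set(tab["SNP"])
    if not common:
        raise DataError("empty SNP intersection across traits after filtering")

    out: list[SummaryStats] = []
    for st, tab in zip(stats, aligned):
        inside = tab["SNP"].isin(common)
        report.add(st.trait, "unmatched", int((~inside).sum()))
        tab = (tab[inside]
               .sort_values(["CHR", "BP", "SNP"], kind="mergesort")
               .reset_index(drop=True))
        out.append(SummaryStats(trait=st.trait, table=tab))
    report.retained = len(out[0].table)
    logger.info("munge complete:\n%s", report)
    return out, report
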