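"""Domain types and I/O for GWAS summary statistics and LD matrices.

This module defines the shared data model used throughout the package:
per-variant association records (:class:`VariantAssociation`), trait-level
containers (:class:`SummaryStats`), pairwise-LD matrices (:class:`LDMatrix`)
and exposure/outcome pairs aligned to a common effect allele
(:class:`HarmonizedVariant`), together with readers and writers for the
canonical tab-separated layouts and the allele-harmonization routine that
every estimator depends on.

Conventions
-----------
* Coordinates are 1-based; chromosomes are stored as strings (``"1"``..
  ``"22"``, ``"X"``).
* Effect sizes are per effect-allele copy: SD units for continuous traits,
  log-odds for binary traits.
* Floats are written with at least 10 significant digits so that a
  write/read round trip preserves values to within printed precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "SummaryStats",
    "LDMatrix",
    "HarmonizedVariant",
    "ConfigurationError",
    "InputError",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "harmonize",
    "harmonize_detailed",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: EAF band inside which a palindromic variant's strand cannot be inferred.
DEFAULT_EAF_AMBIGUITY_BAND = (0.42, 0.58)


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing or malformed."""


class InputError(ValueError):
    """Input data violate a precondition (empty, duplicated, mismatched)."""


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary-statistic row for one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele``;
    ``eaf`` is the effect-allele frequency and may be ``None`` when the
    source GWAS did not report it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise InputError(f"{self.snp_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise InputError(f"{self.snp_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.snp_id}: effect and other allele are identical")
        if self.pos < 1:
            raise InputError(f"{self.snp_id}: position must be >= 1")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise InputError(f"{self.snp_id}: eaf must lie in (0, 1)")
        if not np.isfinite(self.beta):
            raise InputError(f"{self.snp_id}: beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise InputError(f"{self.snp_id}: se must be a positive finite number")
        if not (0.0 < self.pvalue <= 1.0):
            raise InputError(f"{self.snp_id}: pvalue must lie in (0, 1]")
        if not self.n > 0:
            raise InputError(f"{self.snp_id}: sample size must be positive")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except InputError:
            return False
        return True

    @property
    def palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class SummaryStats:
    """Ordered collection of :class:`VariantAssociation` for one trait."""

    trait_name: str
    trait_type: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise InputError(f"unknown trait_type {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise InputError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_name}")
            seen.add(rec.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> VariantAssociation | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStats":
        """Return a new container keeping only ``snp_ids`` (input order kept)."""
        keep = set(snp_ids)
        return SummaryStats(
            self.trait_name, self.trait_type, [r for r in self.records if r.snp_id in keep]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, trait_name: str, trait_type: str
    ) -> "SummaryStats":
        records = []
        for row in frame.itertuples(index=False):
            eaf = getattr(row, "eaf", np.nan)
            records.append(
                VariantAssociation(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.effect_allele).upper(),
                    other_allele=str(row.other_allele).upper(),
                    eaf=None if pd.isna(eaf) else float(eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=float(row.pvalue),
                    n=float(row.n),
                )
            )
        return cls(trait_name, trait_type, records)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    delimiter: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics table into :class:`SummaryStats`.

    ``column_map`` maps canonical names (``snp_id`` .. ``n``) to the file's
    column names; omit it for files already using the canonical header.
    Rows violating the per-variant invariants are dropped with a logged
    count. ``eaf`` is the only optional column.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype={"chrom": str})
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing_src = [src for src in rename if src not in frame.columns]
        if missing_src:
            raise ConfigurationError(
                f"{path}: mapped columns not found in header: {missing_src}"
            )
        frame = frame.rename(columns=rename)
    mandatory = [c for c in CANONICAL_COLUMNS if c != "eaf"]
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")
    if "eaf" not in frame.columns:
        frame["eaf"] = np.nan

    dup = frame["snp_id"].duplicated()
    if dup.any():
        raise InputError(
            f"{path}: duplicate snp_id values: {sorted(frame.loc[dup, 'snp_id'].unique())[:5]}"
        )

    stats = SummaryStats.from_frame(
        frame, trait_name or path.stem, trait_type
    )
    valid = [r for r in stats.records if r.is_valid()]
    n_dropped = len(stats.records) - len(valid)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    if not valid:
        raise InputError(f"{path}: no valid rows after filtering")
    return SummaryStats(stats.trait_name, stats.trait_type, valid)


def write_sumstats(stats: SummaryStats, path: str | Path) -> Path:
    """Write ``stats`` as a tab-separated file with the canonical header."""
    path = Path(path)
    frame = stats.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")
    return path


@dataclass
class LDMatrix:
    """Pairwise r-squared matrix over an ordered set of variants."""

    snp_ids: list[str]
    r2: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise InputError(f"LD matrix shape {self.r2.shape} != ({m}, {m})")
        if self.pos.shape != (m,):
            raise InputError("LD positions length does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-8:
            raise InputError("LD r2 values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_id: str) -> int:
        try:
            return self._lookup[snp_id]
        except AttributeError:
            self._lookup = {s: i for i, s in enumerate(self.snp_ids)}
            return self._lookup[snp_id]

    def contains(self, snp_id: str) -> bool:
        try:
            self.index(snp_id)
        except KeyError:
            return False
        return True

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index(s) for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)], self.pos[idx])


def write_ld(ld: LDMatrix, path: str | Path) -> Path:
    """Write an LD matrix as TSV: a ``#pos`` line, a header of snp_ids,
    then the square r-squared matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#pos\t" + "\t".join(str(int(p)) for p in ld.pos) + "\n")
        fh.write("\t".join(ld.snp_ids) + "\n")
        for row in ld.r2:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    return path


def read_ld(path: str | Path) -> LDMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#pos"):
            raise InputError(f"{path}: expected leading '#pos' line")
        pos = np.array([int(x) for x in first.split("\t")[1:]], dtype=np.int64)
        snp_ids = fh.readline().rstrip("\n").split("\t")
        r2 = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return LDMatrix(snp_ids, r2, pos)


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects aligned to a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    p_exp: float
    eaf_exp: float | None
    beta_out: float
    se_out: float
    p_out: float
    eaf_out: float | None
    palindromic: bool
    flipped: bool
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise InputError(f"{self.snp_id}: standard errors must be positive")

    @property
    def wald_ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def se_wald(self) -> float:
        return self.se_out / abs(self.beta_exp)


def _flip_outcome(v: VariantAssociation) -> tuple[float, float | None]:
    """Outcome beta and EAF re-expressed on the opposite allele."""
    return -v.beta, (None if v.eaf is None else 1.0 - v.eaf)


def harmonize_detailed(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_policy: str = "infer_by_eaf",
    eaf_band: tuple[float, float] = DEFAULT_EAF_AMBIGUITY_BAND,
) -> tuple[list[HarmonizedVariant], list[tuple[str, str]]]:
    """Align exposure and outcome effects to the exposure's effect allele.

    Returns the harmonized pairs plus a list of ``(snp_id, reason)``
    exclusions. Matching is by ``snp_id`` only. For non-palindromic
    variants the outcome alleles may match directly, swapped (beta and EAF
    flipped), or as the reverse-complement pair (strand-flipped); anything
    else is excluded. Palindromic variants are handled per
    ``palindromic_policy``:

    ``infer_by_eaf`` (default)
        keep the variant and align strand by EAF agreement when both EAFs
        lie outside ``eaf_band``; otherwise exclude it as ambiguous.
    ``drop``
        exclude every palindromic variant.
    ``keep``
        trust the reported strands and align by allele letters alone.
    """
    if palindromic_policy not in ("infer_by_eaf", "drop", "keep"):
        raise ConfigurationError(f"unknown palindromic policy {palindromic_policy!r}")
    out_index = outcome._index()
    shared = [r for r in exposure.records if r.snp_id in out_index]
    if not shared:
        raise InputError("no shared snp_ids between exposure and outcome")

    pairs: list[HarmonizedVariant] = []
    excluded: list[tuple[str, str]] = []
    lo, hi = eaf_band
    for e in shared:
        o = out_index[e.snp_id]
        ea, oa = e.effect_allele, e.other_allele
        beta_out, eaf_out = o.beta, o.eaf
        flipped = False
        pal = _is_palindromic(ea, oa)

        if pal:
            if palindromic_policy == "drop":
                excluded.append((e.snp_id, "palindromic_dropped"))
                continue
            if {o.effect_allele, o.other_allele} != {ea, oa}:
                excluded.append((e.snp_id, "allele_mismatch"))
                continue
            if palindromic_policy == "keep":
                if o.effect_allele != ea:
                    beta_out, eaf_out = _flip_outcome(o)
                    flipped = True
            else:  # infer_by_eaf: letters are strand-ambiguous, use EAF only
                if e.eaf is None or o.eaf is None:
                    excluded.append((e.snp_id, "palindromic_missing_eaf"))
                    continue
                if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
                    excluded.append((e.snp_id, "palindromic_ambiguous"))
                    continue
                if (e.eaf < 0.5) != (o.eaf < 0.5):
                    beta_out, eaf_out = _flip_outcome(o)
                    flipped = True
        else:
            o_ea, o_oa = o.effect_allele, o.other_allele
            if {o_ea, o_oa} == {ea, oa}:
                if o_ea != ea:
                    beta_out, eaf_out = _flip_outcome(o)
                    flipped = True
            else:
                c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
                if {c_ea, c_oa} == {ea, oa}:
                    # reported on the other strand
                    if c_ea != ea:
                        beta_out, eaf_out = _flip_outcome(o)
                        flipped = True
                else:
                    excluded.append((e.snp_id, "allele_mismatch"))
                    continue

        pairs.append(
            HarmonizedVariant(
                snp_id=e.snp_id,
                effect_allele=ea,
                other_allele=oa,
                beta_exp=e.beta,
                se_exp=e.se,
                p_exp=e.pvalue,
                eaf_exp=e.eaf,
                beta_out=beta_out,
                se_out=o.se,
                p_out=o.pvalue,
                eaf_out=eaf_out,
                palindromic=pal,
                flipped=flipped,
                chrom=e.chrom,
                pos=e.pos,
            )
        )
    if excluded:
        logger.info(
            "harmonize: excluded %d of %d shared variants", len(excluded), len(shared)
        )
    return pairs, excluded


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindromic_policy: str = "infer_by_eaf",
    eaf_band: tuple[float, float] = DEFAULT_EAF_AMBIGUITY_BAND,
) -> list[HarmonizedVariant]:
    """Harmonize and return only the aligned pairs (see
    :func:`harmonize_detailed` for exclusion reasons)."""
    pairs, _ = harmonize_detailed(exposure, outcome, palindromic_policy, eaf_band)
    return pairs
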