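"""Reading, validating, and pairing per-locus GWAS summary statistics.

The unit of data is one locus (labelled by its candidate gene, e.g. ``FTO``)
in one study: an analyzed sample size ``n`` and a two-sided association
p-value, optionally with the index SNP, per-allele effect and its standard
error. Studies of the same trait family are paired locus-by-locus, with the
"larger" study designated per locus (large meta-analyses occasionally report
a smaller per-SNP sample than an older study for individual SNPs, so the
designation cannot be made per panel).

Files are plain TSV with a header; required columns ``locus_id``, ``trait``,
``n`` and ``p`` (or ``neglog10_p`` for p-values beyond double precision);
optional ``snp_id``, ``effect``, ``se``. ``.`` or an empty cell marks a
missing optional value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, NoOverlapError, ValidationError
from .pvalues import neglog10p_from_p

__all__ = [
    "LocusRecord",
    "StudyPanel",
    "PairedLocus",
    "PairingResult",
    "BestTraitSelection",
    "read_summary_table",
    "write_summary_table",
    "pair_studies",
    "select_min_n_gap",
    "best_trait_per_snp",
    "write_omissions",
    "LIPID_TRAIT_ORDER",
]

#: Canonical lipid trait order used to break exact p-value ties.
LIPID_TRAIT_ORDER = ("TC", "LDL", "HDL", "TG")


@dataclass(frozen=True)
class LocusRecord:
    """One SNP/locus in one study.

    The p-value is stored as ``neglog10_p`` so extreme GWAS tails (p well
    below 1e-308) lose no precision; the ``p`` property converts back and
    may underflow to 0.0 for display only.
    """

    locus_id: str
    trait: str
    n: int
    neglog10_p: float
    snp_id: str | None = None
    effect: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValidationError(f"{self.locus_id}: n must be a positive integer, got {self.n!r}")
        if not (math.isfinite(self.neglog10_p) and self.neglog10_p >= 0.0):
            raise ValidationError(
                f"{self.locus_id}: -log10 p must be finite and >= 0, got {self.neglog10_p!r}"
            )
        if self.se is not None and not (math.isfinite(self.se) and self.se > 0.0):
            raise ValidationError(f"{self.locus_id}: se must be positive, got {self.se!r}")

    @property
    def p(self) -> float:
        """Two-sided p-value (0 if below the double underflow threshold)."""
        return 10.0 ** (-self.neglog10_p)

    @classmethod
    def from_p(cls, locus_id: str, trait: str, n: int, p: float, **kwargs) -> "LocusRecord":
        return cls(locus_id, trait, n, neglog10p_from_p(p), **kwargs)


@dataclass
class StudyPanel:
    """A named study's per-locus records for one trait family."""

    study_label: str
    trait_family: str
    records: list[LocusRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.locus_id, r.trait) for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"{self.study_label}: duplicate (locus_id, trait) keys {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def key_map(self, key: str = "locus") -> dict[str, LocusRecord]:
        """Map pairing key -> record. ``key`` is ``"locus"`` or ``"snp"``."""
        if key not in ("locus", "snp"):
            raise ValidationError(f"pairing key must be 'locus' or 'snp', got {key!r}")
        out: dict[str, LocusRecord] = {}
        for r in self.records:
            k = r.locus_id if key == "locus" else r.snp_id
            if k is None:
                raise ValidationError(f"{self.study_label}: record {r.locus_id} has no snp_id")
            if k in out:
                raise ValidationError(f"{self.study_label}: duplicate pairing key {k!r}")
            out[k] = r
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": r.locus_id,
                "snp_id": r.snp_id,
                "trait": r.trait,
                "n": r.n,
                "p": r.p,
                "neglog10_p": r.neglog10_p,
                "effect": r.effect,
                "se": r.se,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["locus_id", "snp_id", "trait", "n", "p", "neglog10_p", "effect", "se"])


@dataclass(frozen=True)
class PairedLocus:
    """One locus aligned across two studies, larger-study designation resolved."""

    locus_id: str
    larger: LocusRecord
    smaller: LocusRecord
    larger_study_label: str
    tie: bool = False

    def __post_init__(self) -> None:
        if self.larger.n < self.smaller.n:
            raise ValidationError(f"{self.locus_id}: larger.n < smaller.n after designation")

    @property
    def n_gap(self) -> int:
        return self.larger.n - self.smaller.n


@dataclass
class PairingResult:
    """Pairs plus per-locus bookkeeping of everything that was not paired."""

    pairs: list[PairedLocus]
    omitted: list[tuple[str, str, str]]  # (key, study_label, reason)

    def omitted_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omitted, columns=["locus_id", "study_label", "reason"])


_REQUIRED = ("locus_id", "trait", "n")
_OPTIONAL_FLOAT = ("effect", "se")


def read_summary_table(path, study_label: str, trait_family: str) -> StudyPanel:
    """Read one study's TSV into a validated :class:`StudyPanel`.

    Rows violating a record invariant are reported together with their file
    line numbers (header = line 1). Either a ``p`` or a ``neglog10_p``
    column must be present; ``neglog10_p`` wins when both are.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        na_values=["."],
        keep_default_na=False,
        skip_blank_lines=True,
    )
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if "p" not in df.columns and "neglog10_p" not in df.columns:
        missing.append("p (or neglog10_p)")
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[LocusRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            records.append(_parse_row(row))
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return StudyPanel(study_label=study_label, trait_family=trait_family, records=records)


def _parse_row(row: pd.Series) -> LocusRecord:
    def opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
            return None
        return str(v).strip()

    locus_id = opt("locus_id") or ""
    trait = opt("trait") or ""
    n_raw = opt("n")
    if n_raw is None:
        raise ValidationError("missing n")
    try:
        n = int(float(n_raw))
        if float(n_raw) != n:
            raise ValueError
    except ValueError:
        raise ValidationError(f"non-integer n {n_raw!r}") from None

    nl = opt("neglog10_p")
    if nl is not None:
        neglog10_p = float(nl)
    else:
        p_raw = opt("p")
        if p_raw is None:
            raise ValidationError("missing p")
        p = float(p_raw)
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p={p_raw} outside (0, 1]")
        neglog10_p = neglog10p_from_p(p)

    kwargs = {}
    for name in _OPTIONAL_FLOAT:
        v = opt(name)
        kwargs[name] = float(v) if v is not None else None
    return LocusRecord(
        locus_id=locus_id,
        trait=trait,
        n=n,
        neglog10_p=neglog10_p,
        snp_id=opt("snp_id"),
        **kwargs,
    )


def write_summary_table(panel: StudyPanel, path) -> None:
    """Write a panel as TSV. ``neglog10_p`` is written at full precision so
    a read/write round trip is lossless; ``p`` is informational."""
    df = panel.to_frame()
    df["p"] = df["p"].map(lambda v: f"{v:.6g}")
    for col in ("neglog10_p", "effect", "se"):
        df[col] = df[col].map(lambda v: "." if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.17g}")
    df["snp_id"] = df["snp_id"].map(lambda v: "." if v is None else v)
    df.to_csv(path, sep="\t", index=False)


def pair_studies(panel_a: StudyPanel, panel_b: StudyPanel, key: str = "locus") -> PairingResult:
    """Align two panels locus-by-locus with per-locus larger-study designation.

    For each shared pairing key the record with the larger ``n`` becomes the
    "larger" side regardless of which panel it came from. Exact ties take
    ``panel_a`` as larger and carry ``tie=True``. Loci present in only one
    panel — or present with conflicting traits — are omitted and reported.
    """
    if panel_a.trait_family != panel_b.trait_family:
        raise ValidationError(
            f"trait families differ: {panel_a.trait_family!r} vs {panel_b.trait_family!r}"
        )
    map_a = panel_a.key_map(key)
    map_b = panel_b.key_map(key)

    pairs: list[PairedLocus] = []
    omitted: list[tuple[str, str, str]] = []
    for k, rec_a in map_a.items():
        rec_b = map_b.get(k)
        if rec_b is None:
            omitted.append((k, panel_a.study_label, "absent from " + panel_b.study_label))
            continue
        if rec_a.trait != rec_b.trait:
            omitted.append((k, panel_a.study_label, f"trait mismatch ({rec_a.trait} vs {rec_b.trait})"))
            continue
        if rec_a.n > rec_b.n:
            larger, smaller, label, tie = rec_a, rec_b, panel_a.study_label, False
        elif rec_b.n > rec_a.n:
            larger, smaller, label, tie = rec_b, rec_a, panel_b.study_label, False
        else:
            larger, smaller, label, tie = rec_a, rec_b, panel_a.study_label, True
        pairs.append(PairedLocus(k, larger, smaller, label, tie=tie))
    for k in map_b:
        if k not in map_a:
            omitted.append((k, panel_b.study_label, "absent from " + panel_a.study_label))
    if not pairs:
        raise NoOverlapError(
            f"no overlapping loci between {panel_a.study_label} and {panel_b.study_label}"
        )
    return PairingResult(pairs=pairs, omitted=omitted)


def select_min_n_gap(pairs: list[PairedLocus], min_gap: int) -> list[PairedLocus]:
    """Keep pairs whose sample-size gap is at least ``min_gap`` (inclusive).

    Mirrors the selection used for the lipid meta-analyses, where only loci
    with a per-SNP sample-size difference of at least 10,000 individuals
    between the two studies are comparable.
    """
    if min_gap < 0:
        raise ValidationError(f"min_gap must be >= 0, got {min_gap}")
    return [p for p in pairs if p.n_gap >= min_gap]


@dataclass
class BestTraitSelection:
    """Winner records of the per-SNP best-trait selection, plus tie flags."""

    records: list[LocusRecord]
    ties: dict[str, tuple[str, ...]]  # snp_id -> traits sharing the minimal p


def best_trait_per_snp(records: list[LocusRecord]) -> BestTraitSelection:
    """For each SNP keep the single lipid-trait record with the smallest p.

    Lipid panels report every SNP against TC, LDL, HDL and TG; downstream
    comparisons use only the best-associated trait per SNP, and the same
    trait is then looked up in the companion study. Exact p ties are broken
    by the canonical trait order TC, LDL, HDL, TG and flagged.
    """
    order = {t: i for i, t in enumerate(LIPID_TRAIT_ORDER)}
    groups: dict[str, list[LocusRecord]] = {}
    group_order: list[str] = []
    for r in records:
        if r.trait not in order:
            raise ValidationError(
                f"{r.locus_id}: trait {r.trait!r} not one of {LIPID_TRAIT_ORDER}"
            )
        sid = r.snp_id if r.snp_id is not None else r.locus_id
        if sid not in groups:
            groups[sid] = []
            group_order.append(sid)
        groups[sid].append(r)

    winners: list[LocusRecord] = []
    ties: dict[str, tuple[str, ...]] = {}
    for sid in group_order:
        grp = groups[sid]
        best_l = max(r.neglog10_p for r in grp)
        best = [r for r in grp if r.neglog10_p == best_l]
        best.sort(key=lambda r: order[r.trait])
        winners.append(best[0])
        if len(best) > 1:
            ties[sid] = tuple(r.trait for r in best)
    return BestTraitSelection(records=winners, ties=ties)


def write_omissions(result: PairingResult, path) -> None:
    result.omitted_frame().to_csv(path, sep="\t", index=False)
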