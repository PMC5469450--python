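"""Reading, validation and harmonisation of GWAS summary statistics.

Two-sample Mendelian randomisation combines per-variant associations with an
exposure (here: BMI, in units of 5 kg/m^2 per effect allele) and an outcome
(here: Parkinson disease, as per-allele log odds ratios) estimated in separate
studies.  Before any pooling, the two sets of summary statistics must be
expressed with respect to the same effect allele ("harmonisation"): where the
outcome study reported the opposite allele, the sign of its beta is flipped
and its allele frequency complemented.  Palindromic variants (A/T or C/G
pairs) are strand-ambiguous and are resolved — or discarded — using allele
frequencies.

The module also packages the 77-variant BMI instrument panel used throughout
the package as a ready-harmonised fixture (:func:`load_fixture_table1`).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantAssociation",
    "HarmonisedVariant",
    "HarmonisationResult",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_MAF_WINDOW",
    "read_summary_stats",
    "harmonise",
    "load_fixture_table1",
    "write_harmonised_tsv",
    "write_exclusion_report",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Logical -> physical column names, GCTA-COJO style.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "freq",
    "beta": "b",
    "se": "se",
    "p_value": "p",
    "chromosome": "chr",
    "position": "bp",
}

#: Effect-allele-frequency window around 0.5 within which a palindromic
#: variant's strand orientation cannot be resolved from frequency alone.
DEFAULT_MAF_WINDOW: tuple[float, float] = (0.42, 0.58)


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant's summary association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p_value: float
    chromosome: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single A/C/G/T bases "
                f"(got {self.effect_allele!r}/{self.other_allele!r}); indels are not supported"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0 (got {self.se})")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.variant_id}: eaf must be in [0, 1] (got {self.eaf})")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.variant_id}: p_value must be in (0, 1] (got {self.p_value})")
        if self.position is not None and self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1 (1-based)")

    @property
    def palindromic(self) -> bool:
        """True for A/T and C/G allele pairs (strand-ambiguous)."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonisedVariant:
    """A variant with exposure and outcome effects on the same effect allele.

    ``beta_zx`` is the per-allele effect on the exposure, ``beta_zy`` the
    per-allele log odds ratio of the outcome, both reported for the exposure
    study's effect allele.
    """

    variant_id: str
    beta_zx: float
    se_zx: float
    beta_zy: float
    se_zy: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if not self.se_zx > 0:
            raise ValueError(f"{self.variant_id}: se_zx must be > 0")
        if not self.se_zy > 0:
            raise ValueError(f"{self.variant_id}: se_zy must be > 0")


@dataclass
class HarmonisationResult(Sequence):
    """Harmonised variants plus a full accounting of what was not kept.

    Behaves as a sequence of :class:`HarmonisedVariant`; ``excluded`` holds
    ``(variant_id, reason)`` pairs and ``unmatched`` the exposure variants with
    no outcome record, so that matched + excluded + unmatched equals the
    exposure input count.
    """

    variants: list[HarmonisedVariant] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def __getitem__(self, i):
        return self.variants[i]

    def __iter__(self) -> Iterator[HarmonisedVariant]:
        return iter(self.variants)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    report: list[tuple[str, str]] | None = None,
) -> list[VariantAssociation]:
    """Read per-variant summary statistics from a delimited text file.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with one row per variant.
    column_map
        Mapping of logical names (``variant_id``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``p_value``, and
        optionally ``chromosome``, ``position``) to the file's column
        headers.  Defaults to GCTA-COJO style headers.
    sep
        Field delimiter; sniffed from the file when omitted.
    report
        If given, ``(variant_id, reason)`` pairs for every rejected row are
        appended to it.  Rejections are also emitted as warnings.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    KeyError
        If a required mapped column is absent (configuration error).
    ValueError
        If the file contains duplicate variant identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)

    required = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p_value"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise KeyError(
            f"{path.name}: required column(s) {missing} not found; "
            f"available: {list(df.columns)}"
        )
    has_pos = cmap.get("chromosome") in df.columns and cmap.get("position") in df.columns

    records: list[VariantAssociation] = []
    seen: set[str] = set()
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        vid = str(row[cmap["variant_id"]])
        try:
            kwargs = dict(
                variant_id=vid,
                effect_allele=str(row[cmap["effect_allele"]]).strip().upper(),
                other_allele=str(row[cmap["other_allele"]]).strip().upper(),
                eaf=float(row[cmap["eaf"]]),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                p_value=float(row[cmap["p_value"]]),
            )
            if has_pos:
                kwargs["chromosome"] = str(row[cmap["chromosome"]])
                kwargs["position"] = int(float(row[cmap["position"]]))
            rec = VariantAssociation(**kwargs)
        except (TypeError, ValueError) as exc:
            rejected.append((vid, str(exc)))
            continue
        if vid in seen:
            raise ValueError(f"{path.name}: duplicate variant_id {vid!r}")
        seen.add(vid)
        records.append(rec)

    if rejected:
        if report is not None:
            report.extend(rejected)
        warnings.warn(
            f"{path.name}: rejected {len(rejected)} row(s): "
            + "; ".join(f"{v} ({r})" for v, r in rejected[:10]),
            stacklevel=2,
        )
    return records


def _orientation(exp: VariantAssociation, out: VariantAssociation) -> str | None:
    """How the outcome alleles relate to the exposure alleles.

    Returns ``"same"`` (no action), ``"swap"`` (flip beta sign, complement
    eaf) or ``None`` (incompatible allele pair).  Strand flips (complemented
    alleles) are treated as equivalent to their un-complemented counterpart.
    """
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    oc = (COMPLEMENT[o[0]], COMPLEMENT[o[1]])
    if o == e or oc == e:
        return "same"
    if o == (e[1], e[0]) or oc == (e[1], e[0]):
        return "swap"
    return None


def harmonise(
    exposure: Iterable[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    palindrome_policy: str = "frequency_check",
    *,
    maf_window: tuple[float, float] = DEFAULT_MAF_WINDOW,
    proxy_map: Mapping[str, str] | None = None,
) -> HarmonisationResult:
    """Express outcome effects on the exposure's effect allele, per variant.

    Variants are matched by ``variant_id`` (``proxy_map`` maps an exposure
    variant_id to the outcome variant_id standing proxy for it).  If the
    outcome's effect allele is the exposure's other allele, the outcome beta
    sign is flipped and its allele frequency complemented.  Palindromic
    variants are flagged and handled per ``palindrome_policy``:

    ``"drop"``
        exclude every palindromic variant;
    ``"frequency_check"``
        exclude when either study's frequency falls inside ``maf_window``
        (orientation unresolvable near 0.5); otherwise keep, flipping the
        orientation when the two frequencies disagree about which allele is
        the minor one.
    """
    exposure = list(exposure)
    outcome = list(outcome)
    if not exposure or not outcome:
        raise ValueError("exposure and outcome lists must both be non-empty")
    if palindrome_policy not in ("drop", "frequency_check"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    proxy_map = dict(proxy_map or {})
    out_by_id = {v.variant_id: v for v in outcome}

    res = HarmonisationResult()
    lo, hi = maf_window
    for exp in exposure:
        proxy_id = proxy_map.get(exp.variant_id)
        out = out_by_id.get(proxy_id) if proxy_id else out_by_id.get(exp.variant_id)
        if out is None:
            res.unmatched.append(exp.variant_id)
            continue

        orient = _orientation(exp, out)
        if orient is None:
            res.excluded.append((exp.variant_id, "allele mismatch"))
            continue

        beta_zy = out.beta if orient == "same" else -out.beta
        eaf_out = out.eaf if orient == "same" else 1.0 - out.eaf
        palindromic = exp.palindromic

        if palindromic:
            if palindrome_policy == "drop":
                res.excluded.append((exp.variant_id, "palindromic"))
                continue
            if lo <= exp.eaf <= hi or lo <= eaf_out <= hi:
                res.excluded.append(
                    (exp.variant_id, "palindromic with ambiguous allele frequency")
                )
                continue
            # Frequencies on the assumed orientation disagree about the minor
            # allele: the outcome was reported on the opposite strand sense.
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_zy = -beta_zy
                eaf_out = 1.0 - eaf_out

        res.variants.append(
            HarmonisedVariant(
                variant_id=exp.variant_id,
                beta_zx=exp.beta,
                se_zx=exp.se,
                beta_zy=beta_zy,
                se_zy=out.se,
                eaf_exposure=exp.eaf,
                eaf_outcome=eaf_out,
                palindromic=palindromic,
                proxy_of=proxy_id,
            )
        )
    return res


def load_fixture_table1() -> list[HarmonisedVariant]:
    """The packaged 77-variant BMI instrument panel, ready-harmonised.

    Exposure betas are per-allele differences in mean BMI on a 5-kg/m^2
    scale (GIANT consortium); outcome betas are per-allele log odds ratios
    of Parkinson disease (IPDGC meta-analysis), already expressed on the
    exposure effect allele.  rs887912 stands proxy (r^2 = 1.0) for the
    unavailable rs1016287.
    """
    path = resources.files("mrpd.data").joinpath("table1.tsv")
    out: list[HarmonisedVariant] = []
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ea, oa = row["effect_allele"], row["other_allele"]
            out.append(
                HarmonisedVariant(
                    variant_id=row["variant_id"],
                    beta_zx=float(row["beta_bmi"]),
                    se_zx=float(row["se_bmi"]),
                    beta_zy=float(row["beta_pd"]),
                    se_zy=float(row["se_pd"]),
                    eaf_exposure=float(row["eaf"]),
                    palindromic=COMPLEMENT[ea] == oa,
                    proxy_of="rs1016287" if row["variant_id"] == "rs887912" else None,
                )
            )
    return out


_HARMONISED_COLUMNS = [
    "variant_id", "beta_zx", "se_zx", "beta_zy", "se_zy",
    "eaf_exposure", "eaf_outcome", "palindromic", "proxy_of",
]


def write_harmonised_tsv(variants: Iterable[HarmonisedVariant], path: str | Path) -> None:
    """Write a harmonised instrument table as TSV with fixed column order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_HARMONISED_COLUMNS)
        for v in variants:
            w.writerow([getattr(v, c) if getattr(v, c) is not None else "" for c in _HARMONISED_COLUMNS])


def write_exclusion_report(result: HarmonisationResult, path: str | Path) -> None:
    """Write excluded and unmatched variants as a two-column TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["variant_id", "reason"])
        for vid, reason in result.excluded:
            w.writerow([vid, reason])
        for vid in result.unmatched:
            w.writerow([vid, "unmatched"])
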