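"""Data model and I/O for chromosomal-imbalance (CI) matrices and cohort metadata.

A CI is a DNA copy-number gain or loss, either a whole-chromosome-arm
aneuploidy or a focal (sub-arm, band-resolution) change, as produced by
comparative genomic hybridization or by arm-level calling of segmented
copy-number data.  Events are named by canonical strings such as ``+7p``
(gain of the short arm of chromosome 7), ``-18q`` (loss of 18q),
``+8q23-q24`` (focal gain), or ``+12p amp`` (high-level amplification).

The central container, :class:`CIMatrix`, holds a samples x events presence
matrix with codes 0 (absent), 1 (present) and 2 (present as a high-level
amplification; gains only).  On disk the canonical TSV dialect writes a loss
presence as ``-1`` and a gain presence as ``+1``/``+2``; the reader also
accepts unsigned arm columns (header ``13q``) carrying signed codes, which
are split into separate gain and loss events.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = frozenset({-1, 0, 1, 2})
SITES = ("liver", "lung", "brain")
MET_PRIORITY = {"brain": 0, "lung": 1, "liver": 2}
ACROCENTRIC_SHORT = frozenset({"13", "14", "15", "21", "22"})
_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X", "Y")


class CIMatrixParseError(ValueError):
    """Raised when a CI-matrix file violates the format contract."""


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

_EVENT_RE = re.compile(
    r"^([+-])(\d{1,2}|X|Y)([pq])"
    r"((?:\d+(?:\.\d+)?|ter)(?:-(?:[pq])?(?:\d+(?:\.\d+)?|ter))?)?"
    r"( amp)?$"
)


@dataclass(frozen=True, order=True)
class CIEvent:
    """A single chromosomal-imbalance event.

    ``band_interval`` is ``None`` for a whole-arm event; otherwise it is the
    raw band specification (e.g. ``"23-q24"`` for ``+8q23-q24``).
    """

    chromosome: str
    arm: str
    direction: str  # "gain" | "loss"
    band_interval: str | None = None
    high_level: bool = False

    def __post_init__(self):
        if self.chromosome not in _CHROMS:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")
        if self.high_level and self.direction != "gain":
            raise ValueError("high-level amplification must be a gain")

    @property
    def is_arm_level(self) -> bool:
        return self.band_interval is None

    @property
    def sign(self) -> str:
        return "+" if self.direction == "gain" else "-"

    def band_bounds(self) -> tuple[float, float] | None:
        """Numeric (low, high) major-band bounds of a focal event.

        ``ter`` maps to +inf so that terminal intervals compare as extreme.
        """
        if self.band_interval is None:
            return None

        def num(tok: str) -> float:
            return float("inf") if tok == "ter" else float(tok)

        parts = self.band_interval.split("-")
        lo = num(parts[0])
        hi = num(parts[-1].lstrip("pq")) if len(parts) > 1 else lo
        return (min(lo, hi), max(lo, hi))

    @property
    def touches_telomere(self) -> bool:
        return self.band_interval is not None and "ter" in self.band_interval

    def canonical(self) -> str:
        s = f"{self.sign}{self.chromosome}{self.arm}"
        if self.band_interval is not None:
            s += self.band_interval
        if self.high_level:
            s += " amp"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()

    @classmethod
    def parse(cls, label: str) -> "CIEvent":
        m = _EVENT_RE.match(label.strip())
        if m is None:
            raise CIMatrixParseError(f"cannot parse event label {label!r}")
        sign, chrom, arm, bands, amp = m.groups()
        return cls(
            chromosome=chrom,
            arm=arm,
            direction="gain" if sign == "+" else "loss",
            band_interval=bands,
            high_level=amp is not None,
        )


def parse_event(label: str) -> CIEvent:
    """Parse a canonical event string such as ``"+7p"`` or ``"-1p32"``."""
    return CIEvent.parse(label)


# ---------------------------------------------------------------------------
# exclusion mask
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskRule:
    """One excluded region: a whole arm, or a band range on an arm.

    Band-range rules (``band_range`` set) match only focal events whose band
    interval overlaps the range; whole-arm rules match any event on the arm.
    """

    chromosome: str
    arm: str
    band_range: tuple[float, float] | None = None

    def matches(self, event: CIEvent) -> bool:
        if event.chromosome != self.chromosome or event.arm != self.arm:
            return False
        if self.band_range is None:
            return True
        bounds = event.band_bounds()
        if bounds is None:  # whole-arm events survive band-range rules
            return False
        lo, hi = self.band_range
        return bounds[0] <= hi and bounds[1] >= lo


@dataclass(frozen=True)
class ExclusionMask:
    """Regions excluded from CI analysis for technical unreliability.

    The default is the CGH exclusion list: 1p32->pter, the acrocentric short
    arms 13p/14p/15p/21p/22p, telomeric bands, and the constitutive
    heterochromatic blocks on 1q, 9q, 16q and Yq.
    """

    rules: tuple[MaskRule, ...] = (
        MaskRule("13", "p"),
        MaskRule("14", "p"),
        MaskRule("15", "p"),
        MaskRule("21", "p"),
        MaskRule("22", "p"),
        MaskRule("1", "p", (32.0, float("inf"))),
        MaskRule("1", "q", (12.0, 12.999)),
        MaskRule("9", "q", (12.0, 12.999)),
        MaskRule("16", "q", (11.0, 11.999)),
        MaskRule("Y", "q", (12.0, 12.999)),
    )
    exclude_telomeric: bool = True

    def excludes(self, event: CIEvent) -> bool:
        if self.exclude_telomeric and event.touches_telomere:
            return True
        return any(rule.matches(event) for rule in self.rules)


DEFAULT_MASK = ExclusionMask()


# ---------------------------------------------------------------------------
# CI matrix
# ---------------------------------------------------------------------------


@dataclass
class CIMatrix:
    """Samples x events presence matrix with codes {0, 1, 2}."""

    samples: list[str]
    events: list[CIEvent]
    values: np.ndarray  # shape (n_samples, n_events), int8

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.events)):
            raise ValueError("values shape does not match samples x events")
        if len(set(self.samples)) != len(self.samples):
            raise CIMatrixParseError("duplicate sample id")
        labels = [e.canonical() for e in self.events]
        if len(set(labels)) != len(labels):
            raise CIMatrixParseError("duplicate event column")
        bad = ~np.isin(self.values, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CIMatrixParseError(
                f"invalid presence code {self.values[i, j]} for sample "
                f"{self.samples[i]!r}, event {labels[j]!r}"
            )
        for j, ev in enumerate(self.events):
            if ev.direction == "loss" and (self.values[:, j] == 2).any():
                raise CIMatrixParseError(
                    f"high-level code 2 on loss event {labels[j]!r}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def event_labels(self) -> list[str]:
        return [e.canonical() for e in self.events]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.samples, name="sample"),
            columns=self.event_labels,
        )

    def binary(self) -> pd.DataFrame:
        """Presence/absence (amplification collapses onto presence)."""
        return (self.to_frame() > 0).astype(np.int8)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.event_labels.index(label)]

    def subset_samples(self, samples) -> "CIMatrix":
        idx = [self.samples.index(s) for s in samples]
        return CIMatrix(list(samples), list(self.events), self.values[idx])

    # -- mask --------------------------------------------------------------

    def apply_mask(self, mask: ExclusionMask) -> "CIMatrix":
        """Drop events overlapping the mask (idempotent)."""
        keep, dropped = [], []
        for j, ev in enumerate(self.events):
            (dropped if mask.excludes(ev) else keep).append(j)
        if dropped:
            names = [self.events[j].canonical() for j in dropped]
            logger.warning(
                "dropping %d masked event column(s): %s", len(dropped),
                ", ".join(names),
            )
        return CIMatrix(
            list(self.samples), [self.events[j] for j in keep],
            self.values[:, keep],
        )

    # -- I/O ---------------------------------------------------------------

    def write(self, path) -> None:
        """Write the canonical TSV dialect (losses as -1, gains as +1/+2)."""
        frame = self.to_frame().copy()
        for ev in self.events:
            if ev.direction == "loss":
                frame[ev.canonical()] = -frame[ev.canonical()]
        frame.to_csv(path, sep="\t")


_UNSIGNED_RE = re.compile(r"^(\d{1,2}|X|Y)([pq])$")


def read_ci_matrix(path, mask: ExclusionMask | None = DEFAULT_MASK) -> CIMatrix:
    """Read a CI-matrix TSV (first column sample id, header of event labels).

    Signed columns (``+13q``, ``-18q``) carry presence codes; a loss column
    may code presence as either ``1`` or ``-1``.  Unsigned arm columns
    (``13q``) carry signed codes and are split into gain and loss events.
    Events overlapping *mask* are dropped with a logged warning.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise CIMatrixParseError(f"duplicate sample id {dup!r}")
    samples = [str(s) for s in raw.index]

    events: list[CIEvent] = []
    columns: list[np.ndarray] = []
    for col in raw.columns:
        vals = raw[col].to_numpy()
        try:
            vals = vals.astype(np.int64)
        except (TypeError, ValueError) as exc:
            raise CIMatrixParseError(f"non-integer code in column {col!r}") from exc
        bad = ~np.isin(vals, tuple(VALID_CODES))
        if bad.any():
            i = int(np.argwhere(bad)[0][0])
            raise CIMatrixParseError(
                f"invalid code {vals[i]} at sample {samples[i]!r}, column {col!r}"
            )
        uns = _UNSIGNED_RE.match(str(col).strip())
        if uns is not None:
            chrom, arm = uns.groups()
            gain = CIEvent(chrom, arm, "gain")
            loss = CIEvent(chrom, arm, "loss")
            events.append(gain)
            columns.append(np.where(vals > 0, vals, 0))
            events.append(loss)
            columns.append(np.where(vals == -1, 1, 0))
            continue
        ev = CIEvent.parse(str(col))
        if ev.direction == "loss":
            if (vals == 2).any():
                i = int(np.argwhere(vals == 2)[0][0])
                raise CIMatrixParseError(
                    f"invalid code 2 at sample {samples[i]!r}, loss column {col!r}"
                )
            vals = np.abs(vals)  # -1 and 1 both mean "loss present"
        else:
            if (vals < 0).any():
                i = int(np.argwhere(vals < 0)[0][0])
                raise CIMatrixParseError(
                    f"invalid code {vals[i]} at sample {samples[i]!r}, "
                    f"gain column {col!r}"
                )
        events.append(ev)
        columns.append(vals)

    values = (
        np.column_stack(columns).astype(np.int8)
        if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    matrix = CIMatrix(samples, events, values)
    if mask is not None:
        matrix = matrix.apply_mask(mask)
    return matrix


def write_ci_matrix(matrix: CIMatrix, path) -> None:
    matrix.write(path)


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------

TIMINGS = ("primary", "synchronous", "metachronous")


@dataclass
class CohortTable:
    """Per-sample metadata: patient id, lesion site, lesion timing."""

    table: pd.DataFrame  # columns: sample, patient, site, timing [, sex, age]

    def __post_init__(self):
        t = self.table
        required = {"sample", "patient", "site", "timing"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        if t["sample"].duplicated().any():
            raise ValueError("duplicate sample in cohort table")
        bad_site = ~t["site"].isin(("primary",) + SITES)
        if bad_site.any():
            raise ValueError(f"unknown site {t.loc[bad_site, 'site'].iloc[0]!r}")
        bad_t = ~t["timing"].isin(TIMINGS)
        if bad_t.any():
            raise ValueError(f"unknown timing {t.loc[bad_t, 'timing'].iloc[0]!r}")
        prim_mismatch = (t["site"] == "primary") != (t["timing"] == "primary")
        if prim_mismatch.any():
            s = t.loc[prim_mismatch, "sample"].iloc[0]
            raise ValueError(f"sample {s!r}: site=primary iff timing=primary violated")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def metastases(self) -> pd.DataFrame:
        return self.table[self.table["site"] != "primary"]

    def validate_against(self, matrix: CIMatrix) -> None:
        missing = set(matrix.samples) - set(self.samples)
        if missing:
            raise ValueError(f"samples missing from cohort table: {sorted(missing)}")

    def subset(self, samples) -> "CohortTable":
        t = self.table[self.table["sample"].isin(set(samples))]
        return CohortTable(t.reset_index(drop=True))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str, "patient": str}))


# ---------------------------------------------------------------------------
# summaries and cohort filters
# ---------------------------------------------------------------------------


def summarize_ci(matrix: CIMatrix) -> pd.DataFrame:
    """Per-sample CI counts.

    Returns a DataFrame indexed by sample with columns ``n_arm_aneuploidies``,
    ``n_focal``, ``n_losses``, ``n_gains``, ``n_total``.  A high-level
    amplification (code 2) counts once, as a gain.  Short arms of the
    acrocentric chromosomes never count as arm aneuploidies; if such events
    are present (under a custom mask) they fall under ``n_focal`` so that
    ``n_total = n_arm_aneuploidies + n_focal`` always holds.
    """
    present = matrix.values > 0
    is_gain = np.array([e.direction == "gain" for e in matrix.events])
    is_arm = np.array(
        [
            e.is_arm_level
            and not (e.chromosome in ACROCENTRIC_SHORT and e.arm == "p")
            for e in matrix.events
        ]
        if matrix.events else [], dtype=bool,
    )
    n_gains = present[:, is_gain].sum(axis=1) if present.size else np.zeros(len(matrix.samples), int)
    n_total = present.sum(axis=1)
    n_arm = present[:, is_arm].sum(axis=1) if present.size else np.zeros(len(matrix.samples), int)
    return pd.DataFrame(
        {
            "n_arm_aneuploidies": n_arm,
            "n_focal": n_total - n_arm,
            "n_losses": n_total - n_gains,
            "n_gains": n_gains,
            "n_total": n_total,
        },
        index=pd.Index(matrix.samples, name="sample"),
    )


def select_one_met_per_patient(matrix: CIMatrix, meta: CohortTable) -> CohortTable:
    """Retain exactly one metastasis per patient.

    Priority brain > lung > liver (rarer sites first); within a site the
    lesion with the lowest total CI count; ties broken by sample id.
    Patients with only primary samples are excluded with a warning.
    """
    meta.validate_against(matrix)
    counts = summarize_ci(matrix)["n_total"]
    mets = meta.metastases().copy()
    mets = mets[mets["sample"].isin(matrix.samples)]
    all_patients = set(meta.table["patient"])
    kept_rows = []
    for patient, grp in mets.groupby("patient", sort=True):
        grp = grp.assign(
            _prio=grp["site"].map(MET_PRIORITY),
            _ci=grp["sample"].map(counts),
        ).sort_values(["_prio", "_ci", "sample"])
        kept_rows.append(grp.iloc[0][meta.table.columns])
    kept = (
        pd.DataFrame(kept_rows).reset_index(drop=True)
        if kept_rows else meta.table.iloc[0:0]
    )
    skipped = all_patients - set(kept["patient"]) if len(kept) else all_patients
    if skipped:
        logger.warning(
            "excluding %d patient(s) without metastasis samples: %s",
            len(skipped), ", ".join(sorted(map(str, skipped))[:10]),
        )
    return CohortTable(kept)


# ---------------------------------------------------------------------------
# arm definitions and arm-level calling from segmented copy number
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArmDefinition:
    """A chromosome arm as a half-open genomic interval [start, end)."""

    chromosome: str
    arm: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"arm {self.chromosome}{self.arm}: start must precede end"
            )

    @property
    def acrocentric_short(self) -> bool:
        return self.chromosome in ACROCENTRIC_SHORT and self.arm == "p"

    @property
    def length(self) -> int:
        return self.end - self.start


def read_cytoband(path) -> list[ArmDefinition]:
    """Build arm definitions from a UCSC cytoBand.txt-dialect file.

    Columns: chrom, start (0-based), end, band name (e.g. ``p11.2``), stain.
    Bands sharing an arm letter are merged into one arm interval.
    """
    bands = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    bands["chrom"] = bands["chrom"].str.replace("chr", "", regex=False)
    bands["arm"] = bands["band"].str[0]
    bad = ~bands["arm"].isin(("p", "q"))
    if bad.any():
        raise ValueError(f"unparseable band name {bands.loc[bad, 'band'].iloc[0]!r}")
    arms = []
    for (chrom, arm), grp in bands.groupby(["chrom", "arm"], sort=False):
        arms.append(ArmDefinition(chrom, arm, int(grp["start"].min()),
                                  int(grp["end"].max())))
    seen = set()
    for a in arms:
        key = (a.chromosome, a.arm)
        if key in seen:
            raise ValueError(f"duplicate arm {key}")
        seen.add(key)
    return arms


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (ID, chrom, loc.start, loc.end, [num.mark,] seg.mean).

    Coordinates are 1-based inclusive in the file and converted to half-open
    0-based internally.
    """
    seg = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace("_", "."): c for c in seg.columns}
    mapping = {}
    for want, aliases in {
        "sample": ("id", "sample", "sample.id"),
        "chrom": ("chrom", "chromosome", "chr"),
        "start": ("loc.start", "start"),
        "end": ("loc.end", "end"),
        "seg_mean": ("seg.mean", "seg.median", "segmean"),
    }.items():
        for a in aliases:
            if a in cols:
                mapping[want] = cols[a]
                break
        else:
            raise ValueError(f"SEG file lacks a column for {want!r}")
    out = seg[[mapping[k] for k in mapping]].copy()
    out.columns = list(mapping)
    out["chrom"] = out["chrom"].astype(str).str.replace("chr", "", regex=False)
    out["start"] = out["start"].astype(int) - 1  # to half-open
    out["end"] = out["end"].astype(int)
    return out


def call_arm_events(
    segments: pd.DataFrame,
    arms: list[ArmDefinition],
    amp_threshold: float = 0.2,
    coverage_min: float = 0.5,
    alteration_min: float = 0.7,
) -> tuple[CIMatrix, dict[str, str]]:
    """Call arm-level gains/losses for one sample from segmented copy number.

    Per arm: if the covered fraction is below *coverage_min* no call is made
    (flagged ``uncovered``); otherwise the arm is a gain (+1) when at least
    *alteration_min* of the covered length has ``seg_mean >= +amp_threshold``
    (loss symmetric), and a gain becomes a high-level amplification (+2) when
    the length-weighted mean log2 ratio of the gained segments is >= 1.0.

    *segments* uses the half-open internal representation from
    :func:`read_seg` with columns sample, chrom, start, end, seg_mean, and
    must describe a single sample.  Returns a one-sample :class:`CIMatrix`
    of the called (nonzero or uncovered) arms plus a per-arm flag dict.
    """
    if segments.empty:
        raise ValueError("no segments supplied")
    sample_ids = segments["sample"].unique() if "sample" in segments else ["sample"]
    if len(sample_ids) != 1:
        raise ValueError("call_arm_events expects segments from a single sample")
    sample = str(sample_ids[0])

    if (segments["end"] <= segments["start"]).any():
        raise ValueError("segment with non-positive length")
    arm_index: dict[str, list[ArmDefinition]] = {}
    for a in arms:
        arm_index.setdefault(a.chromosome, []).append(a)
    for _, row in segments.iterrows():
        chrom_arms = arm_index.get(str(row["chrom"]))
        if not chrom_arms:
            raise ValueError(f"segment on unknown chromosome {row['chrom']!r}")
        lo = min(a.start for a in chrom_arms)
        hi = max(a.end for a in chrom_arms)
        if row["start"] < lo or row["end"] > hi:
            raise ValueError(
                f"segment {row['chrom']}:{row['start']}-{row['end']} "
                "outside any defined arm"
            )

    events: list[CIEvent] = []
    codes: list[int] = []
    flags: dict[str, str] = {}
    for arm in arms:
        sub = segments[segments["chrom"] == arm.chromosome]
        ov_start = np.maximum(sub["start"].to_numpy(), arm.start)
        ov_end = np.minimum(sub["end"].to_numpy(), arm.end)
        lengths = np.clip(ov_end - ov_start, 0, None).astype(float)
        means = sub["seg_mean"].to_numpy(dtype=float)
        covered = lengths.sum()
        name = f"{arm.chromosome}{arm.arm}"
        if covered / arm.length < coverage_min:
            flags[name] = "uncovered"
            continue
        gained = lengths[means >= amp_threshold]
        lost = lengths[means <= -amp_threshold]
        code = 0
        if gained.sum() / covered >= alteration_min:
            code = 1
            gmeans = means[means >= amp_threshold]
            if np.average(gmeans, weights=gained) >= 1.0:
                code = 2
        elif lost.sum() / covered >= alteration_min:
            code = -1
        if code != 0:
            direction = "gain" if code > 0 else "loss"
            events.append(CIEvent(arm.chromosome, arm.arm, direction))
            codes.append(abs(code) if code != 2 else 2)
    values = np.array([codes], dtype=np.int8) if codes else np.zeros((1, 0), np.int8)
    return CIMatrix([sample], events, values), flags
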