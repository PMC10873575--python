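"""Per-read feature records, bisulfite ground truth, labeling and splitting.

The unit of prediction is a :class:`MethylInstance`: a 13-base motif centered
on a candidate cytosine together with three per-base signal tracks (mean
current, current standard deviation, number of raw signal points) extracted
from a single nanopore read.  Ground truth comes from bisulfite sequencing
summarised per genomic site as methylated/unmethylated read counts
(:class:`BisulfiteSiteRecord`); sites are called positive, negative, or
excluded by coverage and methylation-rate thresholds and those calls are then
attached to every read-level instance at that site.

File formats are plain TSV (gzip-transparent): feature files carry one
instance per row with comma-joined signal tracks; bisulfite reports follow
the Bismark cytosine-report layout (chrom, pos, strand, count_meth,
count_unmeth, context).  Coordinates are 0-based; the motif is reported on
the read strand with the central cytosine at index 6.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "MOTIF_LEN",
    "CENTER",
    "UNLABELED",
    "MethylInstance",
    "BisulfiteSiteRecord",
    "DatasetSplit",
    "FeatureFormatError",
    "read_feature_file",
    "write_feature_file",
    "read_bisulfite_report",
    "write_bisulfite_report",
    "label_sites",
    "attach_labels",
    "split_dataset",
    "class_proportion",
]

MOTIF_LEN = 13
CENTER = MOTIF_LEN // 2  # index 6, the candidate cytosine
UNLABELED = -1

_VALID_BASES = set("ACGTN")
_VALID_CONTEXTS = ("CpG", "CHG", "CHH")


class FeatureFormatError(ValueError):
    """Raised for malformed feature or bisulfite-report rows."""


@dataclass(frozen=True)
class MethylInstance:
    """One per-read candidate 5mC site.

    ``means`` are normalized current means (dimensionless z-scores), ``stds``
    per-base current standard deviations (non-negative), ``lens`` the number
    of raw signal points assigned to each base (>= 1).  ``label`` is 1
    (methylated), 0 (unmethylated), or ``UNLABELED``.
    """

    chrom: str
    pos: int
    strand: str
    read_id: str
    motif: str
    means: tuple[float, ...]
    stds: tuple[float, ...]
    lens: tuple[int, ...]
    label: int = UNLABELED

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.motif) != MOTIF_LEN:
            raise ValueError(
                f"motif must have length {MOTIF_LEN}, got {len(self.motif)}")
        if not set(self.motif) <= _VALID_BASES:
            raise ValueError(f"motif contains invalid bases: {self.motif!r}")
        if self.motif[CENTER] != "C":
            raise ValueError(
                f"motif center (index {CENTER}) must be 'C', got "
                f"{self.motif[CENTER]!r} in {self.motif!r}")
        for name, track in (("means", self.means), ("stds", self.stds),
                            ("lens", self.lens)):
            if len(track) != MOTIF_LEN:
                raise ValueError(
                    f"{name} must have length {MOTIF_LEN}, got {len(track)}")
        if any(s < 0 for s in self.stds):
            raise ValueError("stds must be non-negative")
        if any(l < 1 for l in self.lens):
            raise ValueError("lens must be >= 1")
        if self.label not in (0, 1, UNLABELED):
            raise ValueError(f"label must be 0, 1, or {UNLABELED}")

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    def signal_matrix(self) -> np.ndarray:
        """Return the (3, 13) array of (means, stds, lens) tracks."""
        return np.array([self.means, self.stds, self.lens], dtype=np.float64)


@dataclass(frozen=True)
class BisulfiteSiteRecord:
    """Per-genomic-site bisulfite counts in a cytosine-report-like layout."""

    chrom: str
    pos: int
    strand: str
    count_meth: int
    count_unmeth: int
    context: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("counts must be non-negative")
        if self.context not in _VALID_CONTEXTS:
            raise ValueError(f"context must be one of {_VALID_CONTEXTS}")

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def methylation_rate(self) -> float:
        """count_meth / coverage; undefined (raises) at zero coverage."""
        if self.coverage == 0:
            raise ZeroDivisionError("methylation rate undefined at coverage 0")
        return self.count_meth / self.coverage

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of a dataset."""

    train: list[MethylInstance]
    validation: list[MethylInstance]
    test: list[MethylInstance]

    def __iter__(self) -> Iterator[list[MethylInstance]]:
        return iter((self.train, self.validation, self.test))

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


# ---------------------------------------------------------------------------
# TSV readers / writers (gzip-transparent)

_FEATURE_COLUMNS = ("chrom", "pos", "strand", "read_id", "motif",
                    "means", "stds", "lens", "label")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_feature_row(fields: list[str], lineno: int) -> MethylInstance:
    if len(fields) != len(_FEATURE_COLUMNS):
        raise FeatureFormatError(
            f"line {lineno}: expected {len(_FEATURE_COLUMNS)} columns, "
            f"got {len(fields)}")
    chrom, pos, strand, read_id, motif, means_s, stds_s, lens_s, label_s = fields
    try:
        means = tuple(float(x) for x in means_s.split(","))
        stds = tuple(float(x) for x in stds_s.split(","))
        lens = tuple(int(x) for x in lens_s.split(","))
    except ValueError as exc:
        raise FeatureFormatError(f"line {lineno}: bad numeric field: {exc}")
    if label_s in ("0", "1"):
        label = int(label_s)
    elif label_s in ("-1", ".", "NA"):
        label = UNLABELED
    else:
        raise FeatureFormatError(f"line {lineno}: unknown label {label_s!r}")
    try:
        return MethylInstance(chrom=chrom, pos=int(pos), strand=strand,
                              read_id=read_id, motif=motif, means=means,
                              stds=stds, lens=lens, label=label)
    except ValueError as exc:
        raise FeatureFormatError(f"line {lineno}: {exc}")


def read_feature_file(path: str | Path,
                      strict: bool = True) -> list[MethylInstance]:
    """Read a feature TSV into instances.

    In strict mode (default) any malformed row raises
    :class:`FeatureFormatError` naming the line; in lenient mode malformed
    rows are skipped.
    """
    instances: list[MethylInstance] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                instances.append(_parse_feature_row(line.split("\t"), lineno))
            except FeatureFormatError:
                if strict:
                    raise
    return instances


def write_feature_file(instances: Iterable[MethylInstance],
                       path: str | Path) -> None:
    """Write instances as a feature TSV (inverse of :func:`read_feature_file`)."""
    with _open_text(path, "wt") as fh:
        for inst in instances:
            fh.write("\t".join([
                inst.chrom, str(inst.pos), inst.strand, inst.read_id,
                inst.motif,
                ",".join(repr(float(m)) for m in inst.means),
                ",".join(repr(float(s)) for s in inst.stds),
                ",".join(str(int(l)) for l in inst.lens),
                str(inst.label),
            ]) + "\n")


def read_bisulfite_report(path: str | Path) -> list[BisulfiteSiteRecord]:
    """Read a cytosine-report-like TSV of per-site bisulfite counts."""
    records: list[BisulfiteSiteRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FeatureFormatError(
                    f"line {lineno}: expected 6 columns, got {len(fields)}")
            chrom, pos, strand, n_meth, n_unmeth, context = fields
            try:
                records.append(BisulfiteSiteRecord(
                    chrom=chrom, pos=int(pos), strand=strand,
                    count_meth=int(n_meth), count_unmeth=int(n_unmeth),
                    context=context))
            except ValueError as exc:
                raise FeatureFormatError(f"line {lineno}: {exc}")
    return records


def write_bisulfite_report(records: Iterable[BisulfiteSiteRecord],
                           path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_meth}\t"
                     f"{r.count_unmeth}\t{r.context}\n")


# ---------------------------------------------------------------------------
# Ground-truth labeling

SiteCall = Literal["positive", "negative", "excluded"]


def label_sites(records: Sequence[BisulfiteSiteRecord],
                min_coverage: int = 5,
                pos_rate: float = 0.9,
                coverage_filter_negatives: bool = True,
                ) -> dict[tuple[str, int, str], SiteCall]:
    """Call each bisulfite site positive, negative, or excluded.

    A site is positive when coverage strictly exceeds ``min_coverage`` and
    the methylation rate strictly exceeds ``pos_rate``; negative when its
    rate is exactly 0 (and, by default, the same coverage filter holds —
    a 0% call from one or two reads is not credible, and credible negatives
    are the point of the 0%-rate rule; set ``coverage_filter_negatives=False``
    to accept any covered 0%-rate site).  Everything else, including
    uncovered sites, is excluded.  The three calls partition the input sites.
    """
    calls: dict[tuple[str, int, str], SiteCall] = {}
    for rec in records:
        cov = rec.coverage
        if cov == 0:
            calls[rec.site] = "excluded"
            continue
        rate = rec.methylation_rate
        covered = cov > min_coverage
        if covered and rate > pos_rate:
            calls[rec.site] = "positive"
        elif rate == 0.0 and (covered or not coverage_filter_negatives):
            calls[rec.site] = "negative"
        else:
            calls[rec.site] = "excluded"
    return calls


def attach_labels(instances: Sequence[MethylInstance],
                  labels: dict[tuple[str, int, str], SiteCall],
                  ) -> tuple[list[MethylInstance], dict[str, int]]:
    """Label read-level instances from site calls, dropping uncallable sites.

    Returns the surviving labeled instances and a count summary
    ``{"positive", "negative", "dropped"}``.
    """
    out: list[MethylInstance] = []
    counts = {"positive": 0, "negative": 0, "dropped": 0}
    for inst in instances:
        call = labels.get(inst.site)
        if call == "positive":
            out.append(replace(inst, label=1))
            counts["positive"] += 1
        elif call == "negative":
            out.append(replace(inst, label=0))
            counts["negative"] += 1
        else:
            counts["dropped"] += 1
    return out, counts


def split_dataset(instances: Sequence[MethylInstance],
                  ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> DatasetSplit:
    """Shuffle deterministically and partition into train/validation/test.

    Validation and test sizes are floor allocations of their ratio shares;
    the remainder goes to training, so a 10 000-instance input under 8:1:1
    yields exactly 8000/1000/1000.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    n = len(instances)
    if n < 3:
        raise ValueError(f"need at least 3 instances to split, got {n}")
    total = sum(ratios)
    n_val = n * ratios[1] // total
    n_test = n * ratios[2] // total
    n_train = n - n_val - n_test
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [instances[i] for i in order]
    return DatasetSplit(train=shuffled[:n_train],
                        validation=shuffled[n_train:n_train + n_val],
                        test=shuffled[n_train + n_val:])


def class_proportion(instances: Sequence[MethylInstance] | None = None,
                     *, n_pos: int | None = None,
                     n_neg: int | None = None) -> float:
    """Positive:negative imbalance ratio, (#label==1) / (#label==0).

    Accepts either a collection of labeled instances or explicit counts.
    This is the "Proportion" statistic used to characterise dataset
    imbalance regimes (~0.02 for sparse plant methylomes up to ~1.85 for
    human CpG-rich data).
    """
    if instances is not None:
        n_pos = sum(1 for i in instances if i.label == 1)
        n_neg = sum(1 for i in instances if i.label == 0)
    if n_pos is None or n_neg is None:
        raise ValueError("provide instances or both n_pos and n_neg")
    if n_neg == 0:
        raise ValueError("class proportion undefined with zero negatives")
    return n_pos / n_neg
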