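"""Simulation of a multiplexed barcode-transgenesis experiment.

The generator mirrors the design of a pooled-injection germline
transgenesis experiment in Drosophila:

* a diverse library of fixed-length random DNA barcodes (default
  20,000 x 14 bp) cloned into an integration plasmid;
* injection of the pool into embryos, where each of the ~12-18 pole
  cells founding the germline is an independent integration target and
  an integrating cell receives one barcode drawn uniformly (with
  replacement) from the pool;
* the cross design: only surviving, fertile, male G0 flies found
  scoreable lineages, and up to 10 F1 transgenic progeny per lineage
  are sequenced, each inheriting one insertion from one germ cell
  (siblings may share);
* amplicon sequencing with the construct's primer scheme — four forward
  primers sharing a 3' core but offset by frameshift pads of 0/2/4/6
  bases — uniform per-base substitution errors, and per-sample read
  depths drawn from a negative binomial;
* duplicate-control sample pairs (same template on two plates) and
  blank wells, for plate-level process validation.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Literal, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from tagem.barcode_calling import SampleReadSet
from tagem.detection_eval import Box

__all__ = [
    "BarcodeLibrary",
    "ConstructLayout",
    "DEFAULT_LAYOUT",
    "GermlineSimConfig",
    "EmbryoRecord",
    "SampleRecord",
    "TruthTable",
    "DetectionDataset",
    "generate_library",
    "integration_prob_for_mean",
    "simulate_germline_experiment",
    "synthesize_sample_reads",
    "synthesize_experiment_reads",
    "generate_detection_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# byte -> index in ACGT, used when substituting errors
_BASE_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i

#: Phred+33 character for the constant Q37 base quality.
QUAL_CHAR = chr(37 + 33)


@dataclass(frozen=True)
class BarcodeLibrary:
    """A pool of unique fixed-length DNA barcodes."""

    barcode_length: int
    entries: Tuple[str, ...]
    library_id: str = "library"

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("library entries must be unique")
        for e in self.entries:
            if len(e) != self.barcode_length:
                raise ValueError(
                    f"entry {e!r} is not {self.barcode_length} bp long"
                )
            if set(e) - set("ACGT"):
                raise ValueError(f"entry {e!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.entries)

    def as_matrix(self) -> np.ndarray:
        """Entries packed as an (n, length) uint8 byte matrix."""
        return np.frombuffer(
            "".join(self.entries).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.entries), self.barcode_length)


@dataclass(frozen=True)
class ConstructLayout:
    """Amplicon structure around the barcode.

    A read is ``pad + forward_primer_core + barcode + trailing_flank``,
    where the pad is one of four frameshift pads (lengths 0/2/4/6) that
    stagger the sequencing register to keep early-cycle base diversity
    high on the instrument.
    """

    forward_primer_core: str = "CTTCCAACAACCGGAAGTGA"
    frameshift_pads: Tuple[str, ...] = ("", "AG", "TCGA", "GAAGAG")
    trailing_flank: str = "AAAGCAATAGCATCACAAATTTCACAAAT"
    reverse_primer: str = "ATTTGTGAAATTTGTGATGCTATTGCTTT"

    def __post_init__(self) -> None:
        if sorted(len(p) for p in self.frameshift_pads) != [0, 2, 4, 6]:
            raise ValueError("frameshift pad lengths must be exactly {0, 2, 4, 6}")
        for name in ("forward_primer_core", "trailing_flank", "reverse_primer"):
            seq = getattr(self, name)
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name} contains non-ACGT characters")
        for p in self.frameshift_pads:
            if set(p) - set("ACGT"):
                raise ValueError(f"pad {p!r} contains non-ACGT characters")


DEFAULT_LAYOUT = ConstructLayout()


def generate_library(
    n: int, length: int = 14, seed: Optional[int] = None, library_id: str = "library"
) -> BarcodeLibrary:
    """Draw ``n`` unique uniform-random barcodes of ``length`` bp.

    Duplicates are rejected and redrawn, so the library is collision-free
    by construction.  Requires ``n <= 4**length``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    if n > 4**length:
        raise ValueError(
            f"impossible library: {n} unique barcodes exceed 4^{length} sequences"
        )
    rng = np.random.default_rng(seed)
    seen: Dict[str, None] = {}
    # over-draw in batches; rejection keeps uniformity over distinct k-mers
    while len(seen) < n:
        batch = max(n - len(seen), 64)
        draws = _BASES[rng.integers(0, 4, size=(batch, length))]
        for row in draws.view(f"S{length}").ravel():
            if len(seen) == n:
                break
            bc = row.decode("ascii")
            if bc not in seen:
                seen[bc] = None
    return BarcodeLibrary(
        barcode_length=length, entries=tuple(seen), library_id=library_id
    )


def integration_prob_for_mean(
    target_mean: float, pole_cell_min: int = 12, pole_cell_max: int = 18
) -> float:
    """Per-cell integration probability giving a target conditional mean.

    With N pole cells uniform on [min, max] and each cell integrating
    independently with probability p, the number of integrations B is
    mixed-binomial; this solves for p such that E[B | B >= 1] equals
    ``target_mean`` (the mean insertions per *transgenic-producing*
    embryo).  The reachable range is (1, mean N).
    """
    ns = np.arange(pole_cell_min, pole_cell_max + 1)
    mean_n = ns.mean()
    if not 1.0 < target_mean < mean_n:
        raise ValueError(
            f"target mean must lie in (1, {mean_n}); got {target_mean}"
        )

    def conditional_mean(p: float) -> float:
        p0 = np.mean((1.0 - p) ** ns)
        return p * mean_n / (1.0 - p0)

    return float(
        brentq(lambda p: conditional_mean(p) - target_mean, 1e-9, 1.0 - 1e-12)
    )


@dataclass(frozen=True)
class GermlineSimConfig:
    """Parameters of the simulated injection experiment.

    Defaults follow the pooled-injection study design this package
    analyses: 1,713 injected embryos, half male, adult survival such
    that ~13% of injections yield a scoreable male, ~83% of those
    fertile, 12-18 pole cells per embryo, a >=20,000-barcode pool, up to
    10 progeny sequenced per lineage, ~1,000x mean depth and a 0.5%
    per-base error rate.  ``per_cell_integration_prob=None`` resolves to
    the probability at which transgenic-producing embryos carry 3.9
    independent insertions on average (see
    :func:`integration_prob_for_mean`).
    """

    library: BarcodeLibrary
    n_embryos: int = 1713
    survival_prob: float = 0.26
    male_fraction: float = 0.5
    fertility_prob: float = 0.83
    pole_cell_min: int = 12
    pole_cell_max: int = 18
    per_cell_integration_prob: Optional[float] = None
    progeny_sampled_max: int = 10
    read_depth_mean: float = 1000.0
    read_depth_dispersion: float = 5.0
    per_base_error_rate: float = 0.005
    n_blanks: int = 16
    n_duplicate_controls: int = 7
    blank_mode: Literal["subthreshold", "mixture"] = "subthreshold"
    blank_depth_range: Tuple[int, int] = (10, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("survival_prob", "male_fraction", "fertility_prob",
                     "per_base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        p = self.per_cell_integration_prob
        if p is not None and not 0.0 <= p <= 1.0:
            raise ValueError("per_cell_integration_prob must be in [0, 1]")
        if self.pole_cell_min > self.pole_cell_max:
            raise ValueError("pole_cell_min must be <= pole_cell_max")
        if self.progeny_sampled_max < 1:
            raise ValueError("progeny_sampled_max must be >= 1")
        if self.blank_mode not in ("subthreshold", "mixture"):
            raise ValueError(f"unknown blank_mode {self.blank_mode!r}")

    def resolved_integration_prob(self) -> float:
        if self.per_cell_integration_prob is not None:
            return self.per_cell_integration_prob
        return integration_prob_for_mean(3.9, self.pole_cell_min, self.pole_cell_max)


@dataclass(frozen=True)
class EmbryoRecord:
    embryo_id: str
    survived: bool
    male: bool
    fertile: bool
    true_barcode_set: Tuple[str, ...]  # distinct barcodes, order of first integration

    @property
    def transgenic_lineage(self) -> bool:
        """Scoreable lineage: survived, male, fertile, >=1 integration."""
        return self.survived and self.male and self.fertile and bool(self.true_barcode_set)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    lineage_id: str
    role: Literal["progeny", "duplicate_control", "blank"]
    true_template: Optional[str]


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment."""

    embryos: List[EmbryoRecord]
    samples: List[SampleRecord]

    def transgenic_lineages(self) -> List[EmbryoRecord]:
        return [e for e in self.embryos if e.transgenic_lineage]

    def true_set_sizes(self) -> Dict[str, int]:
        return {
            e.embryo_id: len(e.true_barcode_set) for e in self.transgenic_lineages()
        }


def simulate_germline_experiment(config: GermlineSimConfig) -> TruthTable:
    """Simulate injections, germline integration and the F1 cross design.

    Per embryo: survival ~ Bernoulli(survival_prob), sex ~
    Bernoulli(male_fraction), fertility ~ Bernoulli(fertility_prob);
    pole-cell count uniform on [pole_cell_min, pole_cell_max]; each pole
    cell integrates one library barcode (uniform, with replacement) with
    probability per_cell_integration_prob.  Within-embryo barcode
    collisions are allowed and collapse to one unique barcode.  For each
    transgenic-producing lineage, up to ``progeny_sampled_max`` F1
    samples each inherit one barcode uniformly from the embryo's true
    set.  Duplicate-control pairs share one template; blanks have none.
    """
    rng = np.random.default_rng(config.seed)
    lib = config.library
    p_int = config.resolved_integration_prob()
    n = config.n_embryos
    width = max(4, len(str(n)))

    survived = rng.random(n) < config.survival_prob
    male = rng.random(n) < config.male_fraction
    fertile = rng.random(n) < config.fertility_prob
    pole_cells = rng.integers(config.pole_cell_min, config.pole_cell_max + 1, size=n)

    embryos: List[EmbryoRecord] = []
    samples: List[SampleRecord] = []
    for i in range(n):
        integrating = rng.random(pole_cells[i]) < p_int
        k = int(integrating.sum())
        barcodes = [lib.entries[j] for j in rng.integers(0, len(lib), size=k)]
        true_set = tuple(dict.fromkeys(barcodes))  # dedupe, keep order
        emb = EmbryoRecord(
            embryo_id=f"E{i:0{width}d}",
            survived=bool(survived[i]),
            male=bool(male[i]),
            fertile=bool(fertile[i]),
            true_barcode_set=true_set,
        )
        embryos.append(emb)
        if emb.transgenic_lineage:
            draws = rng.integers(0, len(true_set), size=config.progeny_sampled_max)
            for j, d in enumerate(draws):
                samples.append(
                    SampleRecord(
                        sample_id=f"{emb.embryo_id}_p{j:02d}",
                        lineage_id=emb.embryo_id,
                        role="progeny",
                        true_template=true_set[d],
                    )
                )

    transgenic = [e for e in embryos if e.transgenic_lineage]
    for c in range(config.n_duplicate_controls):
        if transgenic:
            src = transgenic[int(rng.integers(0, len(transgenic)))]
            template = src.true_barcode_set[
                int(rng.integers(0, len(src.true_barcode_set)))
            ]
        else:
            template = lib.entries[int(rng.integers(0, len(lib)))]
        for half in ("a", "b"):
            samples.append(
                SampleRecord(
                    sample_id=f"CTRL{c:02d}_{half}",
                    lineage_id=f"CTRL{c:02d}",
                    role="duplicate_control",
                    true_template=template,
                )
            )
    for b in range(config.n_blanks):
        samples.append(
            SampleRecord(
                sample_id=f"BLANK{b:02d}",
                lineage_id="BLANK",
                role="blank",
                true_template=None,
            )
        )
    return TruthTable(embryos=embryos, samples=samples)


def _apply_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """In-place i.i.d. substitution errors on an ACGT byte matrix."""
    if error_rate <= 0 or mat.size == 0:
        return
    mask = rng.random(mat.shape) < error_rate
    k = int(mask.sum())
    if k == 0:
        return
    shift = rng.integers(1, 4, size=k)
    mat[mask] = _BASES[(_BASE_IDX[mat[mask]] + shift) % 4]


def synthesize_sample_reads(
    sample: SampleRecord,
    layout: ConstructLayout,
    depth: int,
    error_rate: float,
    seed: Optional[int] = None,
    library: Optional[BarcodeLibrary] = None,
    rng: Optional[np.random.Generator] = None,
) -> SampleReadSet:
    """Synthesize amplicon reads for one sample.

    Each read is ``pad + forward_primer_core + barcode + trailing_flank``
    with the frameshift pad chosen uniformly among the four, i.i.d.
    per-base substitution errors at ``error_rate`` and constant Q37
    qualities.  Samples without a template (blanks) draw every read's
    barcode uniformly from ``library`` — an even mixture that cannot
    pass the consensus rule at any realistic depth.
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = SampleReadSet(sample_id=sample.sample_id)
    if depth == 0:
        return out
    if sample.true_template is None:
        if library is None:
            raise ValueError(
                f"sample {sample.sample_id} has no template; a library is "
                "required to synthesize mixture reads"
            )
        bc_idx = rng.integers(0, len(library), size=depth)
        barcodes = [library.entries[i] for i in bc_idx]
    else:
        barcodes = [sample.true_template] * depth
    pad_choice = rng.integers(0, len(layout.frameshift_pads), size=depth)

    reads: List[Tuple[str, str]] = []
    for pi, pad in enumerate(layout.frameshift_pads):
        rows = np.nonzero(pad_choice == pi)[0]
        if rows.size == 0:
            continue
        chunks = [
            pad + layout.forward_primer_core + barcodes[r] + layout.trailing_flank
            for r in rows
        ]
        mat = np.frombuffer("".join(chunks).encode("ascii"), dtype=np.uint8)
        mat = mat.reshape(rows.size, len(chunks[0])).copy()
        _apply_errors(mat, error_rate, rng)
        qual = QUAL_CHAR * mat.shape[1]
        for row in mat.view(f"S{mat.shape[1]}").ravel():
            reads.append((row.decode("ascii"), qual))
    out.reads = reads
    return out


def synthesize_experiment_reads(
    truth: TruthTable,
    layout: ConstructLayout,
    config: GermlineSimConfig,
) -> Iterator[SampleReadSet]:
    """Yield reads for every sample of a simulated experiment.

    Per-sample depths are negative-binomial with the configured mean and
    dispersion; sub-threshold blanks instead draw a small uniform depth.
    Per-sample seeds are spawned from ``config.seed`` so the output is
    bit-identical across runs and independent of consumption order.
    """
    ss = np.random.SeedSequence(config.seed)
    depth_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(len(truth.samples))
    k = config.read_depth_dispersion
    m = config.read_depth_mean
    for sample, child in zip(truth.samples, children):
        if sample.role == "blank" and config.blank_mode == "subthreshold":
            lo, hi = config.blank_depth_range
            depth = int(depth_rng.integers(lo, hi + 1))
        else:
            depth = int(depth_rng.negative_binomial(k, k / (k + m)))
        yield synthesize_sample_reads(
            sample,
            layout,
            depth=depth,
            error_rate=config.per_base_error_rate,
            library=config.library,
            rng=np.random.default_rng(child),
        )


@dataclass
class DetectionDataset:
    """Paired ground-truth and predicted boxes for evaluation fixtures."""

    ground_truth: List[Box]
    predictions: List[Box]


def generate_detection_fixtures(
    n_images: int,
    boxes_per_image: int,
    jitter: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: Optional[int] = None,
    image_size: float = 1024.0,
    box_size: Tuple[float, float] = (40.0, 80.0),
    class_label: str = "embryo",
) -> DetectionDataset:
    """Place non-overlapping ground-truth boxes and derive predictions.

    Ground truth lives on a grid (so boxes never overlap); predictions
    are jittered copies of surviving ground-truth boxes (each dropped
    with probability ``fn_rate``) plus uniformly placed false positives
    (Binomial(n_gt, fp_rate) of them), with uniform confidences.
    """
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    grid = int(np.ceil(np.sqrt(boxes_per_image)))
    cell = image_size / grid
    if box_size[1] > cell:
        raise ValueError("boxes_per_image too large for non-overlapping placement")
    gts: List[Box] = []
    preds: List[Box] = []
    for img in range(n_images):
        image_id = f"img{img:04d}"
        cells = rng.permutation(grid * grid)[:boxes_per_image]
        for c in cells:
            cy, cx = divmod(int(c), grid)
            w = rng.uniform(*box_size)
            h = rng.uniform(*box_size)
            x = cx * cell + rng.uniform(0, cell - w)
            y = cy * cell + rng.uniform(0, cell - h)
            gts.append(Box(image_id, x, y, w, h, class_label=class_label))
            if rng.random() < fn_rate:
                continue
            dx, dy = rng.uniform(-jitter, jitter, size=2) if jitter > 0 else (0.0, 0.0)
            preds.append(
                Box(
                    image_id,
                    x + dx,
                    y + dy,
                    w,
                    h,
                    confidence=float(rng.uniform(0.5, 1.0)),
                    class_label=class_label,
                )
            )
        n_fp = rng.binomial(boxes_per_image, fp_rate)
        for _ in range(n_fp):
            w = rng.uniform(*box_size)
            h = rng.uniform(*box_size)
            preds.append(
                Box(
                    image_id,
                    float(rng.uniform(0, image_size - w)),
                    float(rng.uniform(0, image_size - h)),
                    w,
                    h,
                    confidence=float(rng.uniform(0.1, 0.9)),
                    class_label=class_label,
                )
            )
    return DetectionDataset(ground_truth=gts, predictions=preds)
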