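"""Fragment-frequency training and NP-likeness scoring.

The score contrasts how often each circular fragment (atom signature) occurs
in a natural-product corpus versus a synthetic-molecule corpus.  With

* ``np_i`` / ``sm_i``  — number of *distinct* molecules of each training
  corpus containing fragment ``i`` (document frequency), and
* ``np_t`` / ``sm_t``  — the corpus sizes,

each fragment contributes

    fragment_i = ln( (np_i + alpha) / (sm_i + alpha) * sm_t / np_t )

where ``alpha`` is a pseudo-count (default 1) that keeps the statistic finite
for fragments seen in only one corpus; ``alpha = 0`` reproduces the bare
log-ratio, which is undefined when either count is zero.  A query molecule's
raw score is the sum of the contributions of its atom signatures (every
occurrence counted — term frequency on the query side), and the NP-likeness
score is that sum divided by the number of signatures, i.e. the heavy-atom
count.  The normalisation stops large molecules from accumulating score by
size alone.  Higher means more natural-product-like.

The log-ratio is evaluated as a signed sum of four logarithms, so swapping
the two corpora negates every score bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ModelFormatError, OutputError, TrainingError, UndefinedScoreError
from .records import ScoreFileRecord, SignatureFileRecord
from .signatures import DEFAULT_HEIGHT, decode_signature, DecodedSignature

MODEL_MAGIC = "nplikeness-model"
MODEL_VERSION = 1

DEFAULT_ALPHA = 1.0


@dataclass
class FrequencyIndex:
    """Document frequencies of signatures over one training corpus."""

    counts: dict[str, int]
    total_molecules: int

    def __post_init__(self) -> None:
        if self.total_molecules < 1:
            raise TrainingError("a frequency index needs at least one molecule")

    def count(self, signature: str) -> int:
        return self.counts.get(signature, 0)


@dataclass
class ScorerModel:
    """Paired NP / synthetic indexes plus height and smoothing policy."""

    np_index: FrequencyIndex
    sm_index: FrequencyIndex
    height: int = DEFAULT_HEIGHT
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("pseudo-count alpha must be >= 0")

    def swapped(self) -> "ScorerModel":
        """Model with the two corpora exchanged (scores negate exactly)."""
        return ScorerModel(self.sm_index, self.np_index, self.height, self.alpha)


@dataclass(frozen=True)
class FragmentScore:
    signature: str
    value: float


@dataclass(frozen=True)
class ScoreResult:
    uuid: str
    raw_sum: float
    n_atoms: int
    np_likeness: float


def build_index(records: Sequence[SignatureFileRecord]) -> FrequencyIndex:
    """Document-frequency index: a molecule (uuid) containing a signature
    several times still contributes 1 to that signature's count."""
    if not records:
        raise TrainingError("cannot build an index from an empty signature set")
    uuids: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    counts: dict[str, int] = {}
    for rec in records:
        uuids.add(rec.uuid)
        key = (rec.uuid, rec.signature)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        counts[rec.signature] = counts.get(rec.signature, 0) + 1
    return FrequencyIndex(counts=counts, total_molecules=len(uuids))


def fragment_score(signature: str, model: ScorerModel) -> FragmentScore:
    """Smoothed log-ratio contribution of one fragment.

    Evaluated as ``ln(np_i+a) - ln(sm_i+a) + ln(sm_t) - ln(np_t)`` so the
    statistic is exactly antisymmetric under corpus exchange.
    """
    np_i = model.np_index.count(signature) + model.alpha
    sm_i = model.sm_index.count(signature) + model.alpha
    if np_i <= 0 or sm_i <= 0:
        raise UndefinedScoreError(
            f"fragment score undefined for {signature!r}: zero count with alpha=0"
        )
    # grouped as two differences: each difference negates exactly under a
    # corpus swap, and IEEE addition of negated terms negates the sum exactly
    value = (math.log(np_i) - math.log(sm_i)) + (
        math.log(model.sm_index.total_molecules)
        - math.log(model.np_index.total_molecules)
    )
    return FragmentScore(signature=signature, value=value)


def score_molecules(
    query: Sequence[SignatureFileRecord], model: ScorerModel
) -> list[ScoreResult]:
    """Score query molecules given as pooled signature records.

    Records are grouped by uuid (fragments of one parent pool together);
    duplicate signatures within a molecule are scored per occurrence.  Output
    follows first appearance order of uuids.
    """
    order: list[str] = []
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    cache: dict[str, float] = {}
    for rec in query:
        if rec.uuid not in sums:
            order.append(rec.uuid)
            sums[rec.uuid] = 0.0
            ns[rec.uuid] = 0
        v = cache.get(rec.signature)
        if v is None:
            v = fragment_score(rec.signature, model).value
            cache[rec.signature] = v
        sums[rec.uuid] += v
        ns[rec.uuid] += 1
    return [
        ScoreResult(
            uuid=u, raw_sum=sums[u], n_atoms=ns[u], np_likeness=sums[u] / ns[u]
        )
        for u in order
    ]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: ScorerModel, path: str | Path) -> None:
    """Versioned plain-text container: header, then two count tables."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(f"{MODEL_MAGIC}\tv{MODEL_VERSION}\n")
            fh.write(f"height\t{model.height}\n")
            fh.write(f"alpha\t{model.alpha!r}\n")
            fh.write(f"np_total\t{model.np_index.total_molecules}\n")
            fh.write(f"sm_total\t{model.sm_index.total_molecules}\n")
            for tag, index in (("np", model.np_index), ("sm", model.sm_index)):
                fh.write(f"[{tag}_counts]\t{len(index.counts)}\n")
                for sig in sorted(index.counts):
                    fh.write(f"{sig}\t{index.counts[sig]}\n")
    except OSError as exc:
        raise OutputError(f"cannot write model to {path}: {exc}") from exc


def load_model(path: str | Path) -> ScorerModel:
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ModelFormatError(f"cannot read model {path}: {exc}") from exc
    if not lines or not lines[0].startswith(MODEL_MAGIC):
        raise ModelFormatError(f"{path}: not a {MODEL_MAGIC} file")
    version = lines[0].split("\t")[1]
    if version != f"v{MODEL_VERSION}":
        raise ModelFormatError(
            f"{path}: unsupported model version {version} (expected v{MODEL_VERSION})"
        )
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("["):
        key, _, value = lines[i].partition("\t")
        header[key] = value
        i += 1
    try:
        height = int(header["height"])
        alpha = float(header["alpha"])
        totals = {"np": int(header["np_total"]), "sm": int(header["sm_total"])}
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed header: {exc}") from exc

    tables: dict[str, dict[str, int]] = {}
    current: dict[str, int] | None = None
    for line in lines[i:]:
        # section headers are exactly '[np_counts]\tN' / '[sm_counts]\tN';
        # signature lines also start with '[' but never with these prefixes
        if line.startswith(("[np_counts]\t", "[sm_counts]\t")):
            tag = line[1:3]
            current = tables.setdefault(tag, {})
            continue
        if current is None:
            raise ModelFormatError(f"{path}: counts before any section header")
        sig, _, cnt = line.rpartition("\t")
        try:
            current[sig] = int(cnt)
        except ValueError as exc:
            raise ModelFormatError(f"{path}: bad count line {line!r}") from exc
    if set(tables) != {"np", "sm"}:
        raise ModelFormatError(f"{path}: missing count section(s)")
    return ScorerModel(
        np_index=FrequencyIndex(tables["np"], totals["np"]),
        sm_index=FrequencyIndex(tables["sm"], totals["sm"]),
        height=height,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# fragment inspection and plotting
# ---------------------------------------------------------------------------

def top_fragments(
    model: ScorerModel,
    k: int,
    direction: str = "np_like",
    decode: bool = False,
) -> list[tuple[str, FragmentScore] | tuple[str, FragmentScore, DecodedSignature]]:
    """The ``k`` most NP-like (or most synthetic-like) fragments of the
    training vocabulary, ties broken lexicographically by signature text."""
    if direction not in ("np_like", "synthetic_like"):
        raise ValueError("direction must be 'np_like' or 'synthetic_like'")
    vocab = sorted(set(model.np_index.counts) | set(model.sm_index.counts))
    scored = [(sig, fragment_score(sig, model)) for sig in vocab]
    reverse = direction == "np_like"
    scored.sort(key=lambda p: ((-p[1].value if reverse else p[1].value), p[0]))
    out = scored[: max(k, 0)]
    if decode:
        return [(sig, fs, decode_signature(sig)) for sig, fs in out]
    return list(out)


def plot_score_density(
    results: Mapping[str, Sequence[ScoreResult | ScoreFileRecord | float]],
    path: str | Path,
    bw_method: str = "silverman",
    grid_points: int = 512,
) -> Path:
    """Overlaid Gaussian-kernel score densities, one curve per named set,
    written as PDF.  Degenerate sets (zero variance) are drawn as a narrow
    peak at their value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np
    from scipy.stats import gaussian_kde

    if not results:
        raise ValueError("no score sets to plot")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, values in results.items():
        x = np.asarray(
            [
                v.np_likeness if isinstance(v, ScoreResult)
                else v.score if isinstance(v, ScoreFileRecord)
                else float(v)
                for v in values
            ],
            dtype=float,
        )
        if x.size == 0:
            continue
        if x.size > 1 and np.ptp(x) > 0:
            kde = gaussian_kde(x, bw_method=bw_method)
            bw = kde.factor * x.std(ddof=1)
            grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_points)
            ax.plot(grid, kde(grid), label=name)
        else:
            # all scores identical: a narrow triangular spike
            v = float(x[0])
            eps = max(abs(v) * 1e-3, 1e-3)
            ax.plot([v - eps, v, v + eps], [0.0, 1.0 / eps, 0.0], label=name)
    ax.set_xlabel("NP-likeness score")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    try:
        fig.savefig(path, format="pdf")
    except OSError as exc:
        raise OutputError(f"cannot write plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path


def train(
    np_records: Sequence[SignatureFileRecord],
    sm_records: Sequence[SignatureFileRecord],
    height: int = DEFAULT_HEIGHT,
    alpha: float = DEFAULT_ALPHA,
) -> ScorerModel:
    """Convenience: build both indexes and wrap them in a model."""
    return ScorerModel(
        np_index=build_index(np_records),
        sm_index=build_index(sm_records),
        height=height,
        alpha=alpha,
    )
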