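"""Planted-motif benchmark: consensus regex matches vs exact-p-value PWM hits.

The evaluation re-creates, at synthetic scale, the standard way of judging
how faithfully a consensus sequence summarizes its PWM: occurrence sites
found by the consensus regular expression are compared against "ground
truth" sites found by an exact-p-value PWM scan (p < 1e-5), per motif, by
the area under the precision-recall curve.  Truth sites matched by a
consensus site (exact interval and strand) inherit the PWM hit's
``-log10 p`` significance; consensus sites absent from the truth are false
positives with score 0; unmatched truth sites are misses.  Per-motif auPRCs
are averaged per method and methods are compared by a paired (by motif)
t-test.

The synthetic genome is i.i.d. background sequence with motif instances
sampled column-wise from each PWM and planted non-overlapping at recorded
positions, half of them reverse-complemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethodConfig, convert_motif
from .io import MotifRecord
from .scan import OccurrenceSite, consensus_regex, scan_consensus, scan_pwm

logger = logging.getLogger(__name__)

__all__ = [
    "generate_synthetic_genome",
    "auprc",
    "compare_methods",
    "BenchmarkReport",
]


def generate_synthetic_genome(
    motifs: list[MotifRecord],
    length: int,
    instances_per_motif: int,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background sequence with PWM-sampled instances planted at known sites.

    Returns ``({sequence_id: sequence}, planted)`` where ``planted`` has
    columns motif/start/end/strand.  Instances are sampled column-wise from
    each PWM, placed uniformly at random without overlap, and half are
    planted on the reverse strand.  Deterministic given ``seed``.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    alphabet = motifs[0].alphabet
    n = alphabet.size
    bg = np.full(n, 1.0 / n) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    rng = np.random.default_rng(seed)

    total_width = sum(m.width * instances_per_motif for m in motifs)
    if total_width >= length:
        raise ValueError(
            f"cannot pack {total_width} planted bases into a length-{length} genome"
        )

    chars = np.array(list(alphabet.characters))
    genome = rng.choice(n, size=length, p=bg)

    occupied = np.zeros(length, dtype=bool)
    rows = []
    for motif in motifs:
        k = motif.width
        placed = 0
        attempts = 0
        max_attempts = instances_per_motif * 1000
        while placed < instances_per_motif:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {instances_per_motif} instances of "
                    f"{motif.name} without overlap; genome too dense"
                )
            start = int(rng.integers(0, length - k + 1))
            if occupied[start:start + k].any():
                continue
            instance = np.array(
                [rng.choice(n, p=row) for row in motif.matrix], dtype=np.int64
            )
            strand = "+" if placed % 2 == 0 else "-"
            if strand == "-":
                comp = np.array(
                    [alphabet.index(alphabet.complement(c)) for c in alphabet.characters]
                )
                instance = comp[instance][::-1]
            genome[start:start + k] = instance
            occupied[start:start + k] = True
            rows.append({"motif": motif.name, "start": start, "end": start + k,
                         "strand": strand})
            placed += 1

    sequence = "".join(chars[genome])
    planted = pd.DataFrame(rows, columns=["motif", "start", "end", "strand"])
    planted = planted.sort_values(["motif", "start"]).reset_index(drop=True)
    return {"synth": sequence}, planted


def auprc(predicted: list[OccurrenceSite], truth: list[OccurrenceSite]) -> float | None:
    """Area under the precision-recall curve for consensus sites vs PWM truth.

    Truth sites are the positives; a predicted site matching a truth site
    exactly (sequence, interval, strand) is a true positive and inherits
    the truth site's significance score, any other predicted site is a
    false positive with score 0.  Precision is traced over recall with
    descending score threshold (tied scores enter together) and integrated
    by the trapezoid rule; the curve starts at recall 0 with the precision
    of the highest-scoring group.  Returns None (with a warning) when the
    truth set is empty, since precision-recall is undefined there.
    """
    if not truth:
        logger.warning("auPRC undefined: empty truth set")
        return None
    truth_scores = {t.key: t.score for t in truth}
    n_truth = len(truth_scores)

    seen: set[tuple] = set()
    labels = []
    scores = []
    for site in predicted:
        if site.key in seen:  # the same window cannot count twice
            continue
        seen.add(site.key)
        if site.key in truth_scores:
            labels.append(1)
            scores.append(truth_scores[site.key])
        else:
            labels.append(0)
            scores.append(0.0)
    if not labels:
        return 0.0

    labels_arr = np.asarray(labels)
    scores_arr = np.asarray(scores)
    order = np.argsort(-scores_arr, kind="stable")
    labels_arr = labels_arr[order]
    scores_arr = scores_arr[order]

    tp = np.cumsum(labels_arr)
    fp = np.cumsum(1 - labels_arr)
    # collapse ties: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(scores_arr, append=-np.inf))[0]
    tp = tp[distinct]
    fp = fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_truth

    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


@dataclass
class BenchmarkReport:
    """Per-motif auPRC per method plus paired-test summary.

    ``per_motif`` is a motif x method DataFrame of auPRC values (only
    motifs with non-empty truth).  ``summary`` holds mean and standard
    error per method; ``paired_tests`` one row per method pair with the
    paired t statistic and p-value (NaN p-value when the differences have
    zero variance).  ``excluded`` lists motifs dropped for empty truth.
    """

    per_motif: pd.DataFrame
    summary: pd.DataFrame
    paired_tests: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        out = ["# per-motif auPRC"]
        out.append(self.per_motif.to_csv(sep="\t"))
        out.append("# method summary")
        out.append(self.summary.to_csv(sep="\t"))
        out.append("# paired t-tests")
        out.append(self.paired_tests.to_csv(sep="\t", index=False))
        if self.excluded:
            out.append("# excluded (empty truth): " + ",".join(self.excluded))
        return "\n".join(out)


def compare_methods(
    motifs: list[MotifRecord],
    sequences: dict[str, str],
    configs: list[MethodConfig],
    p_cutoff: float = 1e-5,
    background: np.ndarray | None = None,
) -> BenchmarkReport:
    """Benchmark conversion methods against PWM-scan truth on one genome.

    For each motif: the PWM scan (p < ``p_cutoff``) defines the truth
    sites; each config's consensus regex is scanned and scored by
    :func:`auprc`.  Motifs with empty truth are excluded from pairing and
    listed in the report.
    """
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs for a paired comparison")

    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i}" for i, (lab, _) in enumerate(zip(labels, configs))]

    rows: dict[str, dict[str, float]] = {}
    excluded: list[str] = []
    degenerate: list[str] = []
    for motif in motifs:
        truth = scan_pwm(motif, sequences, p_cutoff=p_cutoff, background=background)
        if not truth:
            excluded.append(motif.name)
            continue
        row = {}
        for label, config in zip(labels, configs):
            columns = convert_motif(motif, config)
            pattern = consensus_regex(columns, motif)
            if all(c.m_star == motif.alphabet.size for c in columns):
                degenerate.append(f"{motif.name}/{label}")
            predicted = scan_consensus(pattern, sequences, motif.alphabet)
            value = auprc(predicted, truth)
            row[label] = np.nan if value is None else value
        rows[motif.name] = row

    if degenerate:
        logger.warning("all-N consensus (matches every window) for: %s",
                       ", ".join(degenerate))
    if len(rows) < 2:
        raise ValueError("fewer than 2 motifs have non-empty truth sets")

    per_motif = pd.DataFrame.from_dict(rows, orient="index")[labels]
    per_motif.index.name = "motif"

    summary = pd.DataFrame(
        {
            "mean_auprc": per_motif.mean(),
            "sem_auprc": per_motif.sem(),
            "n_motifs": per_motif.count(),
        }
    )
    summary.index.name = "method"

    test_rows = []
    for a, b in combinations(labels, 2):
        diff = per_motif[a] - per_motif[b]
        if np.allclose(diff, diff.iloc[0]) and np.isclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff, 0.0):
                logger.warning("zero-variance paired differences for %s vs %s", a, b)
                t_stat, p_val = (0.0, np.nan) if np.allclose(diff, 0) else (np.nan, np.nan)
            else:
                t_stat, p_val = np.nan, np.nan
        else:
            t_stat, p_val = stats.ttest_rel(per_motif[a], per_motif[b])
        test_rows.append(
            {"method_a": a, "method_b": b,
             "mean_diff": float(diff.mean()), "t": float(t_stat), "p_value": float(p_val)}
        )
    paired_tests = pd.DataFrame(test_rows)

    return BenchmarkReport(per_motif=per_motif, summary=summary,
                           paired_tests=paired_tests, excluded=excluded)
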