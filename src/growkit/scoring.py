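"""Pose re-scoring via an external CNN scorer, plus score conversions.

The scorer (e.g. a gnina-style binary) is an optional external dependency
behind a documented command/parse contract: it is invoked in score-only
mode (poses are never moved), and per-pose "CNNscore" (pose probability)
and "CNNaffinity" (predicted pK = -log10 K) values are parsed from its
stdout.  A missing scorer degrades gracefully: records come back unscored
and the pipeline continues.
"""

from __future__ import annotations

import logging
import math
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL
from .errors import ScoringError

logger = logging.getLogger(__name__)

__all__ = ["ScoreRecord", "ScorerCommand", "score_poses", "pk_to_dg",
           "benchmark_stats"]


@dataclass
class ScoreRecord:
    """Per-pose score: CNN pose probability, predicted pK, derived ΔG."""

    pose_id: int
    cnn_pose_score: float | None = None
    cnn_affinity: float | None = None
    dg_pred: float | None = None
    raw_output: str = ""
    error: str | None = None


@dataclass
class ScorerCommand:
    """External scorer invocation/parsing contract.

    The executable is called as
    ``<exe> -r <receptor.pdb> -l <poses.sdf> --score_only`` and its stdout
    is scanned for per-pose ``<score_field> <value>`` and
    ``<affinity_field> <value>`` lines (field names configurable).
    """

    executable: str = "gnina"
    extra_args: tuple[str, ...] = ("--score_only",)
    score_field: str = "CNNscore"
    affinity_field: str = "CNNaffinity"
    timeout: float = 600.0

    def resolve(self) -> str | None:
        exe = Path(self.executable)
        if exe.exists():
            return str(exe)
        return shutil.which(self.executable)


def pk_to_dg(pk: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a predicted pK (-log10 of a binding constant) to a binding
    free energy: ΔG = -R·T·ln(10)·pK, in kcal/mol."""
    if not math.isfinite(pk):
        raise ScoringError("pK must be finite")
    return -GAS_CONSTANT_KCAL * temperature * math.log(10.0) * pk


def _parse_scorer_output(text: str, cmd: ScorerCommand) -> list[dict[str, float]]:
    """Per-pose blocks of field/value pairs from scorer stdout."""
    records: list[dict[str, float]] = []
    current: dict[str, float] = {}
    pattern = re.compile(
        rf"({re.escape(cmd.score_field)}|{re.escape(cmd.affinity_field)})"
        r"[:=\s]+(-?\d+(?:\.\d+)?)")
    for line in text.splitlines():
        m = pattern.search(line)
        if not m:
            continue
        field, value = m.group(1), float(m.group(2))
        if field in current:
            records.append(current)
            current = {}
        current[field] = value
    if current:
        records.append(current)
    return records


def score_poses(poses_sdf: str | Path, receptor_pdb: str | Path,
                scorer: ScorerCommand | None = None,
                n_poses: int | None = None,
                temperature: float = DEFAULT_TEMPERATURE) -> list[ScoreRecord]:
    """Re-score poses with the external scorer (score-only: coordinates are
    read, never modified).  With no resolvable scorer, unscored records are
    returned and a warning logged; a failing scorer captures the error per
    pose instead of raising."""
    scorer = scorer or ScorerCommand()
    poses_sdf = Path(poses_sdf)
    if n_poses is None:
        n_poses = _count_sdf_records(poses_sdf)
    if n_poses == 0:
        return []

    exe = scorer.resolve()
    if exe is None:
        logger.warning("scorer %r not found; returning unscored records",
                       scorer.executable)
        return [ScoreRecord(pose_id=i) for i in range(n_poses)]

    argv = [exe, "-r", str(receptor_pdb), "-l", str(poses_sdf),
            *scorer.extra_args]
    try:
        proc = subprocess.run(argv, capture_output=True, text=True,
                              timeout=scorer.timeout)
    except (OSError, subprocess.TimeoutExpired) as exc:
        logger.warning("scorer invocation failed: %s", exc)
        return [ScoreRecord(pose_id=i, error=str(exc)) for i in range(n_poses)]
    if proc.returncode != 0:
        err = f"scorer exited {proc.returncode}: {proc.stderr.strip()[:500]}"
        logger.warning(err)
        return [ScoreRecord(pose_id=i, error=err, raw_output=proc.stdout)
                for i in range(n_poses)]

    parsed = _parse_scorer_output(proc.stdout, scorer)
    if len(parsed) != n_poses:
        raise ScoringError(
            f"scorer returned {len(parsed)} records for {n_poses} poses; "
            f"raw output retained:\n{proc.stdout[:2000]}")
    records = []
    for i, rec in enumerate(parsed):
        pk = rec.get(scorer.affinity_field)
        records.append(ScoreRecord(
            pose_id=i,
            cnn_pose_score=rec.get(scorer.score_field),
            cnn_affinity=pk,
            dg_pred=pk_to_dg(pk, temperature) if pk is not None else None,
            raw_output=proc.stdout if i == 0 else ""))
    return records


def _count_sdf_records(path: Path) -> int:
    if not path.exists():
        raise ScoringError(f"poses file not found: {path}")
    return sum(1 for line in path.read_text().splitlines()
               if line.strip() == "$$$$")


def benchmark_stats(predicted: list[float],
                    experimental: list[float]) -> dict[str, float | None]:
    """RMSE, mean unsigned error and squared Pearson correlation between
    predicted and experimental binding free energies (kcal/mol)."""
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape:
        raise ScoringError("predicted/experimental length mismatch")
    if p.size < 2:
        raise ScoringError("need at least two pairs")
    diff = p - e
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mue = float(np.mean(np.abs(diff)))
    r2: float | None
    if np.std(p) == 0.0 or np.std(e) == 0.0:
        r2 = None
    else:
        r = float(np.corrcoef(p, e)[0, 1])
        r2 = r * r
    return {"rmse": rmse, "mue": mue, "r2": r2}
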