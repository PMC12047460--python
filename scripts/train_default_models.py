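"""Train the default per-sequence-type classifiers shipped with the package.

The training corpus is synthetic: mixed-sequence wide-morphology ectopy at
moderate burden, with normally and aberrantly conducted premature atrial
beats and broadband noise bursts supplying hard negatives. Seeds are fixed
so the committed models are exactly reproducible:

    python scripts/train_default_models.py [--seed 2026] [--out src/ectopy/models]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from ectopy.beat_detection import beats_from_annotations, mark_noise
from ectopy.config import PipelineConfig
from ectopy.io_signals import preprocess
from ectopy.morphology import SEQ_TYPES, harvest_training_features, train_model
from ectopy.synth_ecg import SyntheticConfig, simulate

TRAIN_RECORDS = 8
RECORD_S = 600.0


def build_corpus(seed: int, cfg: PipelineConfig):
    pooled = {s: ([], []) for s in SEQ_TYPES}
    for i in range(TRAIN_RECORDS):
        sc = SyntheticConfig(
            duration=RECORD_S,
            heart_rate=60.0 + 5.0 * (i % 4),
            target_burden_pct=15.0,
            seq_mix=(0.50, 0.10, 0.25, 0.15),
            pac_rate_per_min=3.0,
            pac_aberrant=(i % 2 == 0),
            noise_bursts=(1, 2.0, 2000.0),
            seed=seed + i,
        )
        res = simulate(sc)
        work = preprocess(res.signal, cfg.preprocess.band_lo,
                          cfg.preprocess.band_hi, cfg.preprocess.target_fs)
        beats = beats_from_annotations(res.annotations, work)
        noise = mark_noise(res.signal, beats, cfg.noise)
        got = harvest_training_features(work, beats, noise,
                                        res.truth.v_times, cfg)
        for s in SEQ_TYPES:
            pooled[s][0].extend(got[s][0])
            pooled[s][1].extend(got[s][1])
    return pooled


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2026)
    ap.add_argument("--out", default=str(Path(__file__).resolve().parents[1]
                                         / "src" / "ectopy" / "models"))
    args = ap.parse_args()
    cfg = PipelineConfig()
    pooled = build_corpus(args.seed, cfg)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for seq in SEQ_TYPES:
        feats, labs = pooled[seq]
        model = train_model(feats, labs, seq, seed=args.seed)
        path = out / f"default_{seq}.json"
        model.to_json(str(path))
        print(f"{seq}: n={len(labs)} pos={sum(labs)} "
              f"threshold={model.decision_threshold:.4f} -> {path}")


if __name__ == "__main__":
    main()
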