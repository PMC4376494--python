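#!/usr/bin/env python
"""Optional benchmark on locally supplied DRIVE/STARE directories.

Not part of acceptance: it requires the datasets to be downloaded separately.
Given a directory of fundus images plus matching ground-truth (and optional
FOV) masks, it runs the full pipeline on every image and prints per-image
TPR / FPR / accuracy plus the averages.

Example (DRIVE test set):
    python scripts/benchmark_datasets.py \
        --images DRIVE/test/images --truth DRIVE/test/1st_manual \
        --fov DRIVE/test/mask --out results/drive.json
"""

import argparse
import json
from pathlib import Path

from vesselem import PipelineConfig, run_pipeline

IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".ppm", ".gif", ".jpg", ".jpeg"}


def find_match(stem: str, directory: Path):
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() in IMAGE_SUFFIXES and path.stem.startswith(stem.split("_")[0]):
            return path
    return None


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--images", type=Path, required=True)
    parser.add_argument("--truth", type=Path, required=True)
    parser.add_argument("--fov", type=Path, default=None)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    config = PipelineConfig.from_yaml(args.config) if args.config else PipelineConfig()
    rows = []
    for image_path in sorted(args.images.iterdir()):
        if image_path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        truth_path = find_match(image_path.stem, args.truth)
        if truth_path is None:
            print(f"skipping {image_path.name}: no ground truth found")
            continue
        fov_path = find_match(image_path.stem, args.fov) if args.fov else None
        result = run_pipeline(image_path, fov=fov_path, truth=truth_path, config=config)
        m = result.metrics
        rows.append({"image": image_path.name, "tpr": m.tpr, "fpr": m.fpr,
                     "accuracy": m.accuracy})
        print(f"{image_path.name}  TPR {m.tpr:.4f}  FPR {m.fpr:.4f}  "
              f"ACC {m.accuracy:.4f}")

    if rows:
        avg = {key: sum(r[key] for r in rows) / len(rows)
               for key in ("tpr", "fpr", "accuracy")}
        print(f"\naverage over {len(rows)} images:  TPR {avg['tpr']:.4f}  "
              f"FPR {avg['fpr']:.4f}  ACC {avg['accuracy']:.4f}")
        if args.out:
            args.out.parent.mkdir(parents=True, exist_ok=True)
            args.out.write_text(json.dumps({"per_image": rows, "average": avg},
                                           indent=2) + "\n")


if __name__ == "__main__":
    main()
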