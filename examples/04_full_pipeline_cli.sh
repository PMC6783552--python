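#!/usr/bin/env bash
# Full shell workflow: simulate -> run pipeline -> inspect metrics.
set -euo pipefail

out=$(mktemp -d)
atacmix simulate --cells 300 --peaks 1000 --dropout 0.4 --seed 0 --out "$out/sim"
atacmix -v run --in "$out/sim/corrupted" \
  --labels "$out/sim/corrupted/labels.tsv" \
  --k 3 --quick --epochs 100 --seed 0 --no-filters \
  --out "$out/run"
echo "outputs:"
ls "$out/run"
cat "$out/run/metrics.json"
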