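#!/usr/bin/env bash
# The same pipeline from the shell: simulate a scenario bundle, compute one
# statistic, and run a full Monte Carlo test writing a result JSON.
set -euo pipefail

out=$(mktemp -d)

retrolink simulate --preset linkage --seed 3 --out "$out/scenario"

retrolink stats --which x2 \
  --assembly "$out/scenario/assembly.tsv" --map "$out/scenario/marey.tsv" \
  --parents "$out/scenario/parents.tsv" --retro "$out/scenario/retrocopies.tsv"

retrolink test --which x2 --iterations 1000 --alpha 0.05 --seed 3 \
  --assembly "$out/scenario/assembly.tsv" --map "$out/scenario/marey.tsv" \
  --parents "$out/scenario/parents.tsv" --retro "$out/scenario/retrocopies.tsv" \
  --out "$out/x2_result.json" --null-out "$out/x2_null.tsv"

cat "$out/x2_result.json"
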