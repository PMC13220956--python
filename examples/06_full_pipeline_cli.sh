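#!/bin/sh
# Run the whole synthetic pipeline end to end through the CLI.
# Outputs (DE tables, consensus GMT, per-cell calls, region scores,
# interaction tests, concordance and overlap reports) land under ./demo_run.
set -e
senescreen all --seed 1 --outdir demo_run
ls demo_run
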