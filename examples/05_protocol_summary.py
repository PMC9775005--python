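"""The multi-group evaluation protocol with a mean ± sd summary.

Draws one 29-healthy / 26-depressed cohort, samples independent 8+8
subject groups, splits each 7:1 into source and target, and runs every
adaptation method on identical images.  The full 11-group protocol is
what scripts/acceptance.py reproduces; three groups keep this demo at
about a minute on one CPU.
"""

from eegtransfer import benchmark
from eegtransfer.evaluate import summarize

results = benchmark.run_protocol(methods=("dan", "dann", "deepcoral"),
                                 n_groups=3, seed=0)
df = summarize(results)

print("per-group final target accuracy:")
grid = df.pivot(index="group_id", columns="method", values="final_accuracy")
print(grid.round(3).to_string())

print("\ncross-group summary (mean ± sample sd):")
for _, row in df.attrs["summary"].iterrows():
    sd = 0.0 if row["n"] < 2 else row["sd"]
    print(f"  {row['method']:>10}: {100 * row['mean']:.1f} ± {100 * sd:.1f} %  "
          f"(n={int(row['n'])})")

print("\nEach group is an independent random source→target subject draw, so")
print("the spread reflects how much a new pair of subjects can differ.")
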