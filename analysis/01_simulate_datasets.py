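"""Generate the study's three synthetic data sets and write them to results/data.

1. A forward simulation of the affinity model itself (1,200 genes, 20
   conditions, growth rates 0.12-0.66 /h, 25% measurement noise): the
   positive control in which roughly half the genes have constant
   affinities and should emerge as growth-correlated.
2. The half-coordinated benchmark: 1,200 proteins, half on the shared
   normalized line (slope 1, intercept 0.5), half flat, 25% noise.
3. A row-shuffled copy of the benchmark: the permutation null.
"""

from pathlib import Path

from proteome_allocation import NoiseSpec, example_model, shuffle_dataset, simulate_from_model, simulate_half_coordinated, write_dataset

SEED = 20160413
OUT = Path("results/data")


def main() -> None:
    model = example_model(n_genes=1200, n_conditions=20, seed=SEED)
    model_data = simulate_from_model(model, NoiseSpec(cv=0.25, seed=SEED))
    write_dataset(model_data, OUT, prefix="model_sim")
    print(f"model simulation: {model_data.n_proteins} proteins, "
          f"{model_data.n_conditions} conditions, "
          f"growth rates {model_data.growth_rates.min():.2f}-{model_data.growth_rates.max():.2f} /h")

    benchmark = simulate_half_coordinated(n_proteins=1200, noise=NoiseSpec(cv=0.25, seed=SEED))
    write_dataset(benchmark, OUT, prefix="benchmark")
    n_coord = (benchmark.protein_meta["true_class"] == "coordinated").sum()
    print(f"half-coordinated benchmark: {n_coord}/{benchmark.n_proteins} proteins on the shared line")

    shuffled = shuffle_dataset(benchmark, seed=SEED)
    write_dataset(shuffled, OUT, prefix="shuffled")
    print("row-shuffled null written")


if __name__ == "__main__":
    main()
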