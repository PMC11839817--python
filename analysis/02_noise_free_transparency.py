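"""Measurement-chain transparency on noise-free subjects.

Ten synthetic subjects are generated with every noise source disabled and
pushed through the full chain: EDF-grade continuous signal -> resampling ->
zero-phase 1-30 Hz filtering -> robust referencing -> epoching -> baseline
correction -> linked-mastoid referencing -> amplitude rejection -> per-level
averaging -> N1/P2 peak measurement -> slope regression. The recovered
slopes are compared with the slopes of the injected amplitude series for
all 9 component x channel cells; agreement within 0.001 uV/dB shows the
pipeline itself neither inflates nor deflates the loudness dependence.
"""

from pathlib import Path

from ldaep.experiments import noise_free_recovery

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = noise_free_recovery(seed=7, n_subjects=10)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "noise_free_recovery.tsv", sep="\t", index=False)
    worst = df["abs_error"].max()
    print(df.groupby(["channel", "component"])["abs_error"].max()
          .to_string(float_format="%.2e"))
    print(f"\nworst-case slope error over {df.shape[0]} cells: "
          f"{worst:.2e} uV/dB (transparency bound 1e-3).")


if __name__ == "__main__":
    main()
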