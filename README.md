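# riboselect

Analysis toolkit for **selective ribosome profiling** of translocon
accessory factors.

In a selective profiling experiment, ribosome-protected mRNA footprints
are sequenced from two pools: the total ribosome population (**input**)
and an affinity-purified subpopulation bound by a factor of interest
(**IP**). Comparing the two localizes *where along each message* — and
therefore at what nascent-chain length — the factor engages translating
ribosomes. `riboselect` takes footprints from paired input/IP libraries
(raw transcript-coordinate reads or pre-assigned per-codon A-site
counts) and computes:

* per-read-length **A-site offsets** calibrated from 3-nt periodicity,
  and A-site codon assignment;
* transcript abundance in **TPM** and transcript-level enrichment
  `log2(TPM_IP / TPM_input)`, median-centred across the transcriptome,
  with per-transcript chi-squared tests and Benjamini–Hochberg
  correction;
* **codon-resolved interaction profiles**
  `e_c = log2((n_IP,c/N_IP + β) / (n_input,c/N_input + β))`
  per replicate, aggregated as mean and range, smoothed with a running
  mean;
* **engagement-onset calls**: the first codon where the smoothed profile
  rises a set fraction of the way from its baseline to its plateau and
  stays up — the nascent-chain length at which the factor arrives;
* the **nascent-chain ↔ lumenal-residue map**: with Δ ≈ 55 residues of
  nascent chain buried in the ribosome exit tunnel and SEC61 channel, a
  chain of length L on a precursor with signal peptide ending at residue
  `sp_end` has exposed lumenal residues `sp_end+1 .. L−Δ`;
* topology-stratified comparisons: enrichment versus the length of the
  longest lumenal (translocated) segment, factor-vs-factor comparisons
  and volcano tables.

A first-class synthetic-data module generates topology-annotated
transcriptomes (secretory, membrane and cytosolic classes, including a
designated high-abundance GRP94-like transcript of 803 residues with
signal peptide 1–21) and paired input/IP libraries under an explicit
engagement model — capture probability steps from a baseline to
`baseline × fold` at the onset codon and persists to termination — so
the entire pipeline runs and is validated without downloading anything.

## Worked example

One command simulates an experiment and runs every stage:

```bash
riboselect run --seed 1 --outdir demo/
```

`demo/enrichment.tsv` then ranks the GRP94-like positive control far
above the background transcriptome (top three rows by centred
enrichment, seed 1):

```
transcript_id     class  n_input  n_ip  log2_enrichment_centred    p_adj
       GRP94L secretory     7246 20561                    1.673 0.000000
       T00160 cytosolic       36    49                    0.697 0.340746
       T00255 secretory       57    72                    0.500 0.377772
```

and `demo/engagement.tsv` holds the onset call:

```
transcript_id  onset_codon  lumenal_start  lumenal_end  buried_offset  plateau_level
       GRP94L          206             22          151             55          2.081
```

Read: the factor was detected arriving when the nascent GRP94-like chain
was ~206 residues long (simulated truth: 204, within the 15-codon
smoothing window). At that point residues 22–151 of the precursor are
exposed in the ER lumen (206 − 55 = 151; the cleaved signal peptide
occupies residues 1–21). The plateau of ~2.1 log2 units reflects the
simulated four-fold IP capture gain (log2 4 = 2).

The same stages are available piecewise (`riboselect simulate`,
`calibrate`, `quantify`, `profile`, `report`) and as library functions:

```python
import riboselect as rs

dataset = rs.simulate(rs.SimulationConfig(seed=1))
table = rs.enrichment_table(dataset.counts, dataset.annotation)
call = rs.call_engagement(dataset.counts, "GRP94L", dataset.annotation)
rs.map_chain_length_to_lumenal(161, sp_end=21)   # -> (22, 106)
rs.map_residue_to_chain_length(149)              # -> 204
```

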