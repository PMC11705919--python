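# Commented template for `raretaxa run --config <file>`.
# Paths are resolved relative to the working directory.

# --- inputs -----------------------------------------------------------
otu_table: data/otu_table.tsv      # TSV, OTUs in rows, samples in header
metadata: data/metadata.tsv        # sample_id, site, health (H/M)
env_table: data/env_table.tsv      # sample_id + soil indicators
taxonomy: data/taxonomy.tsv        # optional; 2-column lineage or 7-column ranks

# --- outputs ----------------------------------------------------------
output_dir: raretaxa_out           # all stage outputs + manifest.json

# --- preprocessing ----------------------------------------------------
seed: 0                            # one top-level seed; stages derive theirs
min_reads: 20                      # drop OTUs with fewer total reads
rarefaction_depth: null            # null = minimum sample total
filter_before_rarefy: false        # default order: rarefy, then filter
abundance_mode: pooled             # pooled | mean relative abundance

# --- co-occurrence network --------------------------------------------
r_threshold: 0.65                  # |Spearman r| must exceed this
alpha: 0.05                        # BH-adjusted p must be below this

# --- OPLS-DA ----------------------------------------------------------
vip_threshold: 1.0                 # differential screening: VIP > this
n_permutations: 200                # label-permutation test size

# --- threshold indicator analysis -------------------------------------
titan_variable: null               # null = first indicator column
titan_subset: AT                   # AT | IT | RT | all
min_split: 3                       # minimum samples on each split side
titan_n_perm: 250                  # permutations per taxon
titan_n_boot: 0                    # bootstrap replicates (0 = skip)

# --- stage toggles ----------------------------------------------------
stages: [partition, network, oplsda, traits, titan, soilfun]
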