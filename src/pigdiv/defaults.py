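"""Single table of analysis defaults shared by the API and the CLI.

Every threshold used anywhere in the pipeline is declared here once so
that tests (and users) can assert on them in one place.
"""

from __future__ import annotations

# Sample-level QC
SAMPLE_CALL_RATE_MIN = 0.90
HET_SD = 3.0
DUP_MATCH_MIN = 0.99
PARENT_OFFSPRING_PI_HAT = 0.5
PI_HAT_TOL = 0.15
SEX_F_FEMALE_MAX = 0.2
SEX_F_MALE_MIN = 0.8

# SNP-level QC
SNP_CALL_RATE_MIN = 0.98
MAF_MIN = 0.03
HWE_P_MIN = 1e-6

# ROH calling
ROH_MIN_SNPS = 50
ROH_MIN_LENGTH_KB = 1000.0
ROH_WINDOW = 50
ROH_MAX_HET_PER_WINDOW = 1
ROH_MAX_MISSING_PER_WINDOW = 1
SHORT_ROH_MB = 5.0
SHARED_ROH_MIN_OVERLAP_BP = 500_000

# Genome constants (autosomal genome length used by F_ROH)
GENOME_LENGTH_KB = 2_808_525.0
AUTOSOMES = tuple(str(c) for c in range(1, 19))

# LD / phase
LD_MAX_DIST_BP = 10_000_000
LD_BIN_BP = 100_000
THIN_KEEP_EVERY = 10
PHASE_HEADLINE_DIST_BP = 50_000
ADJACENT_R2_THRESHOLDS = (0.2, 0.3)

# Ne
CM_PER_MB = 1.0
GRID_STEP1_MAX = 10      # t = 1..10 by 1
GRID_STEP5_MAX = 100     # t = 15..100 by 5
GRID_STEP50_MAX = 1000   # t = 150..1000 by 50

# EM for two-locus haplotype frequencies
EM_TOL = 1e-10
EM_MAX_ITER = 1000
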