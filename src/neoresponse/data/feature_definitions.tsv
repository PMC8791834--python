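name	modality	source	direction_note
age	clinical	clinical_table	age at diagnosis (years)
tumour_size	clinical	clinical_table	largest tumour diameter (mm)
grade	clinical	clinical_table	histological grade 1-3; higher toward pCR
er_status	clinical	clinical_table	ER positive = 1; negative toward pCR
her2_status	clinical	clinical_table	HER2 positive = 1
ln_involvement	clinical	clinical_table	nodal involvement at diagnosis; positive toward residual disease
tmb	DNA	dnafeat.compute_tmb	mutations per Mb; higher toward pCR
pct_subclonal	DNA	dnafeat.pct_subclonal	% subclonal mutations; higher toward residual disease
n_neoantigens	DNA	dnafeat.filter_neoantigens	filtered neoepitope count; higher toward pCR
hrd_score	DNA	dnafeat.compute_hrd	TAI+LOH+LST scar sum; higher toward pCR
cna_fraction	DNA	dnafeat.genome_altered_fraction	fraction genome at non-ploidy CN; higher toward pCR
tp53_mutated	DNA	dnafeat.driver_flags	TP53 somatic mutation flag; toward pCR
pik3ca_mutated	DNA	dnafeat.driver_flags	PIK3CA somatic mutation flag; toward residual disease
hla_loh	DNA	dnafeat.call_hla_loh	any HLA class I allelic loss; toward residual disease
nonclock_fraction	DNA	dnafeat.normalize_exposures	1 - clock signature weight; higher toward pCR
sig3_exposure	DNA	dnafeat.normalize_exposures	log2 HRD-signature exposure vs clock signature
ggi_score	RNA	rnafeat.single_sample_score	genomic grade index enrichment; higher toward pCR
esc_score	RNA	rnafeat.single_sample_score	embryonic stem-cell module enrichment; higher toward pCR
stat1_score	RNA	rnafeat.single_sample_score	STAT1 immune module enrichment; higher toward pCR
taxane_metagene	RNA	rnafeat.taxane_metagene	mitotic minus ceramide metagene; higher toward pCR
cytolytic_score	RNA	rnafeat.cytolytic_score	geomean GZMA/PRF1 TPM; higher toward pCR
danaher_cd8	RNA	rnafeat.danaher_scores	CD8 T cell marker log-geomean; higher toward pCR
danaher_mast	RNA	rnafeat.danaher_scores	mast cell marker log-geomean; higher toward residual disease
t_dysfunction	RNA	external_input	T cell dysfunction score; higher toward residual disease
t_exclusion	RNA	external_input	T cell exclusion score; higher toward residual disease
esr1_log_tpm	RNA	expression_matrix	log2 ESR1 TPM
pgr_log_tpm	RNA	expression_matrix	log2 PGR TPM
erbb2_log_tpm	RNA	expression_matrix	log2 ERBB2 TPM
lymphocyte_density	DigPath	pathfeat.knn_density	median per-cell kNN density (px^-2); higher toward pCR
lymphocyte_fraction	DigPath	pathfeat.cell_fractions	lymphocyte fraction of classified cells; higher toward pCR
anthracycline	treatment	clinical_table	received anthracycline
anti_her2	treatment	clinical_table	received anti-HER2 therapy
taxane_first	treatment	clinical_table	taxane given first
anthracycline_first	treatment	clinical_table	anthracycline given first
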