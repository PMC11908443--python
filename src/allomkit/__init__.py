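"""allomkit — height-diameter allometry and biomass uncertainty for
tropical forest inventories.

The pipeline: read or simulate an inventory → fit and rank candidate
height-diameter models → validate (Graybill, Theil, mixed models, PGLS) →
predict heights with local and published models → propagate into tree- and
plot-level aboveground biomass → decompose estimation errors by tree-size
class → translate biomass revisions into carbon stocks.
"""

from .data_model_io import (AssignmentReport, DataError, ForestDataset,
                            ForestType, FormatError, TreeRecord,
                            WoodDensityTable, assign_wood_density,
                            read_inventory, read_wood_density, write_inventory)
from .hd_allometry import (FitOptions, HDFit, HDModelSpec, adj_pseudo_r2, aic,
                           fit_all_models, fit_model, get_model,
                           model_registry, rank_models, ranking_table)
from .diagnostics import (MixedFitResult, ObsPredRegression, PGLSResult,
                          TheilDecomposition, fit_species_mixed, graybill_test,
                          obs_vs_pred, pagel_lambda, pgls_fit,
                          phylo_covariance, taxon_maxima, theil_decomposition)
from .height_prediction import (GUYANA_SHIELD, PANTROPICAL, ErrorSummary,
                                PublishedHeightModel, compare_height_models,
                                error_summary, predict_height,
                                published_models, stratified_errors)
from .biomass import (BIOMASS_EQUATIONS, BiomassEquation, PlotBiomass,
                      biomass_error_comparison, carbon_accounting,
                      correction_factor, get_equation, plot_biomass, tree_agb)
from .synthetic_data import (PRESETS, ConfigError, StandConfig, StandTruth,
                             generate_phylogeny, generate_stand,
                             generate_wood_density_table, terra_firme_like,
                             varzea_like)

__version__ = "0.1.0"
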