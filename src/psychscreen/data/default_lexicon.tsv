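term_id	pattern	match_mode	case_mode	domain	collocate	exclusion_cues
anxiety	anxiety	exact_token	insensitive	mental_health
depressed	depressed	exact_token	insensitive	mental_health
sad	sad	exact_token	insensitive	mental_health
angry	angry	exact_token	insensitive	mental_health
neurovegetative	neurovegetative	exact_token	insensitive	mental_health
schizoaffective	schizoaffective	exact_token	insensitive	mental_health
substance	substance	exact_token	insensitive	substance_use
abuse	abuse	prefix_token	insensitive	substance_use
addict	addict	prefix_token	insensitive	substance_use
aa	AA	exact_token	exact	substance_use		amino,acid,african,american
sober	sober	prefix_token	insensitive	substance_use
cocaine	cocaine	exact_token	insensitive	substance_use
heroin	heroin	exact_token	insensitive	substance_use
crack	crack	exact_token	insensitive	substance_use
mushrooms	mushrooms	exact_token	insensitive	substance_use
prison	prison	exact_token	insensitive	legal_history
jail	jail	prefix_token	insensitive	legal_history
homeless	homeless	prefix_token	insensitive	social_determinants
shelter	shelter	exact_token	insensitive	social_determinants
stamps	stamps	exact_token	insensitive	social_determinants	food:2:preceding
stolen	stolen	exact_token	insensitive	legal_history
tox	tox	exact_token	insensitive	substance_use
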