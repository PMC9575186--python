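gene	class
MOFTT001	basal-like
MOFTT002	classical
MOFTT003	basal-like
MOFTT004	classical
MOFTT005	basal-like
MOFTT006	classical
MOFTT007	basal-like
MOFTT008	classical
MOFTT009	basal-like
MOFTT010	classical
MOFTT011	basal-like
MOFTT012	classical
MOFTT013	basal-like
MOFTT014	classical
MOFTT015	basal-like
MOFTT016	classical
MOFTT017	basal-like
MOFTT018	classical
MOFTT019	basal-like
MOFTT020	classical
MOFTT021	basal-like
MOFTT022	classical
MOFTT023	basal-like
MOFTT024	classical
MOFTT025	basal-like
MOFTT026	classical
MOFTT027	basal-like
MOFTT028	classical
MOFTT029	basal-like
MOFTT030	classical
MOFTT031	basal-like
MOFTT032	classical
MOFTT033	basal-like
MOFTT034	classical
MOFTT035	basal-like
MOFTT036	classical
MOFTT037	basal-like
MOFTT038	classical
MOFTT039	basal-like
MOFTT040	classical
MOFTT041	basal-like
MOFTT042	classical
MOFTT043	basal-like
MOFTT044	classical
MOFTT045	basal-like
MOFTT046	classical
MOFTT047	basal-like
MOFTT048	classical
MOFTT049	basal-like
MOFTT050	classical
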