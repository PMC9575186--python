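gene	class
MOFTS001	normal
MOFTS002	activated
MOFTS003	normal
MOFTS004	activated
MOFTS005	normal
MOFTS006	activated
MOFTS007	normal
MOFTS008	activated
MOFTS009	normal
MOFTS010	activated
MOFTS011	normal
MOFTS012	activated
MOFTS013	normal
MOFTS014	activated
MOFTS015	normal
MOFTS016	activated
MOFTS017	normal
MOFTS018	activated
MOFTS019	normal
MOFTS020	activated
MOFTS021	normal
MOFTS022	activated
MOFTS023	normal
MOFTS024	activated
MOFTS025	normal
MOFTS026	activated
MOFTS027	normal
MOFTS028	activated
MOFTS029	normal
MOFTS030	activated
MOFTS031	normal
MOFTS032	activated
MOFTS033	normal
MOFTS034	activated
MOFTS035	normal
MOFTS036	activated
MOFTS037	normal
MOFTS038	activated
MOFTS039	normal
MOFTS040	activated
MOFTS041	normal
MOFTS042	activated
MOFTS043	normal
MOFTS044	activated
MOFTS045	normal
MOFTS046	activated
MOFTS047	normal
MOFTS048	activated
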