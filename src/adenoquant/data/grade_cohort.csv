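# 3-month cohort grades reconstructed from printed percentages (smallest consistent n)
mouse_id,grade
adm3m_1,0
adm3m_2,I
adm3m_3,I
adm3m_4,II
adm3m_5,II
adm3m_6,II
adm3m_7,III
adm3m_8,III
adm3m_9,III
adm3m_10,III
adm3m_11,III
adm3m_12,III
adm3m_13,III
adm3m_14,III
adm3m_15,III
adm3m_16,III
adm3m_17,III
adm3m_18,III
adm3m_19,III
adm3m_20,III
adm3m_21,III
adm3m_22,III
adm3m_23,III
adm3m_24,III
adm3m_25,III
adm3m_26,III
adm3m_27,III
adm3m_28,III
adm3m_29,III
adm3m_30,III
adm3m_31,III
adm3m_32,III
adm3m_33,III
adm3m_34,III
adm3m_35,III
adm3m_36,III
adm3m_37,III
adm3m_38,III
adm3m_39,III
adm3m_40,III
adm3m_41,III
adm3m_42,III
adm3m_43,III
adm3m_44,III
adm3m_45,III
adm3m_46,III
adm3m_47,III
adm3m_48,III
adm3m_49,III
adm3m_50,III
adm3m_51,III
adm3m_52,III
adm3m_53,III
adm3m_54,III
adm3m_55,III
adm3m_56,III
adm3m_57,III
adm3m_58,III
adm3m_59,III
adm3m_60,III
adm3m_61,III
adm3m_62,III
adm3m_63,III
adm3m_64,III
adm3m_65,III
adm3m_66,III
adm3m_67,III
adm3m_68,III
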