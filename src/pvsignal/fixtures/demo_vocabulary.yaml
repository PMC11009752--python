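# Demonstration vocabulary: inhaled muscarinic-antagonist products and a
# compact cardiac-disorder term set.  Real regulatory term lists (MedDRA)
# are licensed and must be supplied by the user in this same layout.
drugs:
  tiotropium:
    class: LAMA
    ingredients: [tiotropium]
    synonyms:
      - tiotropium
      - tiotropium bromide
      - tiotropium bromide anhydrous
      - tiotropium bromide monohydrate
      - spiriva
  aclidinium:
    class: LAMA
    ingredients: [aclidinium]
    synonyms:
      - aclidinium
      - aclidinium bromide
      - tudorza pressair
  glycopyrronium:
    class: LAMA
    ingredients: [glycopyrronium]
    synonyms:
      - glycopyrronium
      - glycopyrronium bromide
      - glycopyrrolate
      - seebri
  umeclidinium:
    class: LAMA
    ingredients: [umeclidinium]
    synonyms:
      - umeclidinium
      - umeclidinium bromide
      - incruse ellipta
  ipratropium:
    class: SAMA
    ingredients: [ipratropium]
    synonyms:
      - ipratropium
      - ipratropium bromide
      - ipratropium bromide anhydrous
      - atrovent
  indacaterol:
    class: LABA
    ingredients: [indacaterol]
    synonyms: [indacaterol, indacaterol maleate]
  formoterol:
    class: LABA
    ingredients: [formoterol]
    synonyms: [formoterol, formoterol fumarate]
  vilanterol:
    class: LABA
    ingredients: [vilanterol]
    synonyms: [vilanterol, vilanterol trifenatate]
  glycopyrronium_indacaterol:
    class: LAMA/LABA
    ingredients: [glycopyrronium, indacaterol]
    synonyms:
      - glycopyrronium/indacaterol
      - indacaterol/glycopyrronium
      - ultibro breezhaler
      - utibron neohaler
  glycopyrronium_formoterol:
    class: LAMA/LABA
    ingredients: [glycopyrronium, formoterol]
    synonyms:
      - glycopyrronium/formoterol
      - glycopyrrolate/formoterol
      - bevespi aerosphere
  umeclidinium_vilanterol:
    class: LAMA/LABA
    ingredients: [umeclidinium, vilanterol]
    synonyms:
      - umeclidinium/vilanterol
      - umeclidinium bromide/vilanterol
      - anoro ellipta
  glycopyrronium_indacaterol_mometasone:
    class: LAMA/LABA/ICS
    ingredients: [glycopyrronium, indacaterol, mometasone]
    synonyms:
      - glycopyrronium/indacaterol/mometasone
      - enerzair breezhaler
  glycopyrronium_formoterol_budesonide:
    class: LAMA/LABA/ICS
    ingredients: [glycopyrronium, formoterol, budesonide]
    synonyms:
      - glycopyrronium/formoterol/budesonide
      - budesonide/glycopyrrolate/formoterol
      - breztri aerosphere
  umeclidinium_vilanterol_fluticasone:
    class: LAMA/LABA/ICS
    ingredients: [umeclidinium, vilanterol, fluticasone furoate]
    synonyms:
      - umeclidinium/vilanterol/fluticasone furoate
      - fluticasone furoate/umeclidinium/vilanterol
      - trelegy ellipta

event_groups:
  cardiac_disorders:
    label: Cardiac disorders (broad, SOC-like)
    terms:
      - atrial fibrillation
      - atrial flutter
      - supraventricular tachycardia
      - ventricular tachycardia
      - ventricular extrasystoles
      - tachycardia
      - bradycardia
      - palpitations
      - arrhythmia
      - atrioventricular block
      - cardiac arrest
      - cardiac failure
      - cardiac failure congestive
      - cardiac failure acute
      - left ventricular failure
      - cardiogenic shock
      - myocardial infarction
      - acute myocardial infarction
      - angina pectoris
      - acute coronary syndrome
      - coronary artery disease
      - myocardial ischaemia
      - cardiomegaly
      - cardiomyopathy
      - pericarditis
      - pericardial effusion
      - mitral valve incompetence
  arrhythmias:
    label: Cardiac arrhythmias (narrow, SMQ-like)
    terms:
      - atrial fibrillation
      - atrial flutter
      - supraventricular tachycardia
      - ventricular tachycardia
      - ventricular extrasystoles
      - tachycardia
      - bradycardia
      - palpitations
      - arrhythmia
      - atrioventricular block
      - cardiac arrest
  cardiac_failure:
    label: Cardiac failure (narrow, SMQ-like)
    terms:
      - cardiac failure
      - cardiac failure congestive
      - cardiac failure acute
      - left ventricular failure
      - cardiogenic shock
  ischemic_heart_disease:
    label: Ischemic heart disease (narrow, SMQ-like)
    terms:
      - myocardial infarction
      - acute myocardial infarction
      - angina pectoris
      - acute coronary syndrome
      - coronary artery disease
      - myocardial ischaemia
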