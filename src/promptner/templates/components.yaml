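# Default per-entity prompt component texts.
# task_description / output_format / input_prefix are the "basic" components;
# task_guidance / disambiguation_rule are the "advanced" components.
rare_disease:
  task_description: "Identify the names of rare diseases from the following text."
  output_format: "Output only the exact rare disease names without any additional changes. If there are multiple rare diseases, separate their names with commas. If there is no rare disease, output 'none'."
  input_prefix: "The text from which you need to extract the names of rare diseases is:"
  task_guidance: "A rare disease is a health condition that affects a small percentage of the population. In the U.S., a disease is considered rare if it affects fewer than 200,000 people. In European Union, a disease is considered rare if it affects fewer than 1 in 2,000 people."
  disambiguation_rule: "Treat abbreviations as separate rare disease names. Do not identify regular diseases as rare diseases."
disease:
  task_description: "Identify the names of diseases from the following text."
  output_format: "Output only the exact disease names without any additional changes. If there are multiple diseases, separate their names with commas. If there is no disease, output 'none'."
  input_prefix: "The text from which you need to extract the names of diseases is:"
  task_guidance: "A disease is a condition of the body or mind that impairs normal functioning and is characterized by specific signs and symptoms. Diseases can be caused by a variety of factors, including infections, genetic mutations, environmental factors, and lifestyle choices."
  disambiguation_rule: "Differentiate between rare diseases and diseases. A rare disease is a health condition that affects a small percentage of the population. Rare diseases are a subset of diseases. Only output diseases, not rare diseases."
sign:
  task_description: "Identify the names of signs from the following text."
  output_format: "Output only the exact sign names without any additional changes. If there are multiple signs, separate their names with commas. If there is no sign, output 'none'."
  input_prefix: "The text from which you need to extract the names of signs is:"
  task_guidance: "A sign of a disease is the objective evidence of disease that can be observed or detected by someone other than the individual affected by the disease. It includes measurable indicators such as physical findings, laboratory test results, and imaging studies, which provide concrete evidence of a medical condition."
  disambiguation_rule: "Differentiate between signs and symptoms. Symptoms are subjective experiences of disease reported by the patient and cannot be directly measured by healthcare providers. Only output signs, not symptoms."
symptom:
  task_description: "Identify the names of symptoms from the following text."
  output_format: "Output only the exact symptom names without any additional changes. If there are multiple symptoms, separate their names with commas. If there is no symptom, output 'none'."
  input_prefix: "The text from which you need to extract the names of symptoms is:"
  task_guidance: "A symptom is the subjective experience reported by the patient, which cannot be directly observed or measured by others. They reflect what the patient feels, such as pain, fatigue, or nausea. Symptoms are experienced internally and rely on the patient's description."
  disambiguation_rule: "Differentiate between symptoms and signs. Signs are objective indicators of a disease that can be observed, measured, or detected by someone other than the patient, such as a doctor or medical professional. Only output symptoms, not signs."
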